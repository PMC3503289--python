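"""End-to-end orchestration: synth -> fit -> scale -> simulate.

One :func:`run_pipeline` call reproduces the whole workflow: generate (or
load) fixed-bed conversion data, estimate (Km, Vmax, k2) per inlet
concentration from the linearized integrated-MM regression, form the
dimensionless groups (phi, beta, lambda), solve the steady bead
reaction-diffusion problem per operating point (optionally the transient
too), and write every table plus a manifest recording the configuration
hash, seed, versions and per-stage status. Deterministic stages are
bit-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bead_pde import (
    AxiMesh,
    effectiveness_factor,
    steady_axisymmetric,
    transient_solve,
    write_field_csv,
)
from .fixedbed import FitResult, estimate_km_vmax, write_fit_table
from .kinetics import MMKinetics, read_conversion_csv, write_conversion_csv
from .scaling import BeadTransport, make_groups
from .synthetic import (
    DEFAULT_S0_GRID,
    DEFAULT_SEED,
    DEFAULT_T_GRID,
    ScenarioSpec,
    generate_series,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for one pipeline run (serializable to YAML).

    Physical constants default to the reference operating point: a 2 mm
    alginate bead (radius 0.1 cm), substrate diffusivity 7.8e-8 cm^2/min,
    a 60 cm^3 bed of voidage 0.42 and an enzyme load of 0.081 g/L.
    """

    # physical constants
    bead_radius_cm: float = 0.1
    ds_cm2_per_min: float = 7.8e-8
    dp_cm2_per_min: float | None = None
    voidage: float = 0.42
    reactor_volume_cm3: float = 60.0
    enzyme_load_g_per_L: float = 0.081
    # data source: either a CSV of observations or a synthetic scenario
    input_csv: str | None = None
    true_km_g_per_L: float = 3.38
    true_vmax_g_per_L_s: float = 0.134
    s0_grid: tuple[float, ...] = DEFAULT_S0_GRID
    t_grid: tuple[float, ...] = DEFAULT_T_GRID
    noise_cv: float = 0.0
    seed: int = DEFAULT_SEED
    replicates: int = 1
    # simulation settings
    mesh_n: int = 32
    lam: float = 1.0
    transient: bool = False
    tau_end: float = 10.0
    n_snapshots: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "s0_grid", tuple(float(v) for v in self.s0_grid))
        object.__setattr__(self, "t_grid", tuple(float(v) for v in self.t_grid))
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(f"input CSV does not exist: {self.input_csv}")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["s0_grid"] = list(data["s0_grid"])
        data["t_grid"] = list(data["t_grid"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        data = asdict(self)
        data["s0_grid"] = list(data["s0_grid"])
        data["t_grid"] = list(data["t_grid"])
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()

    def bead_transport(self) -> BeadTransport:
        return BeadTransport(
            r=self.bead_radius_cm, ds=self.ds_cm2_per_min, dp=self.dp_cm2_per_min
        )

    def scenario(self) -> ScenarioSpec:
        return ScenarioSpec(
            true_kinetics=MMKinetics.from_seconds(
                km=self.true_km_g_per_L, vmax_per_s=self.true_vmax_g_per_L_s
            ),
            s0_grid=self.s0_grid,
            t_grid=self.t_grid,
            noise_cv=self.noise_cv,
            seed=self.seed,
            replicates=self.replicates,
        )


def _s0_tag(s0: float) -> str:
    return f"{s0:g}".replace(".", "p")


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages, halting on the first failure.

    Returns the manifest (also written to ``<outdir>/manifest.json``); on a
    stage failure the exception propagates after the partial manifest is
    persisted with that stage marked failed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(outdir / "run.log")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("immobead")
    root.addHandler(log_file)
    manifest: dict = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "immobead_version": __version__,
        "stages": [],
    }

    def record(name: str, status: str, outputs: list[str]) -> None:
        manifest["stages"].append(
            {"name": name, "status": status, "outputs": outputs}
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    cfg.to_yaml(outdir / "config.yaml")
    try:
        # -- stage 1: data --------------------------------------------------
        if cfg.input_csv is not None:
            series = read_conversion_csv(cfg.input_csv)
            logger.info("loaded %d series from %s", len(series), cfg.input_csv)
        else:
            series = generate_series(cfg.scenario())
            logger.info(
                "generated %d series (noise_cv=%g, seed=%d)",
                len(series), cfg.noise_cv, cfg.seed,
            )
        write_conversion_csv(series, outdir / "conversions.csv")
        record("data", "ok", ["conversions.csv", "config.yaml"])

        # -- stage 2: fit ---------------------------------------------------
        fits: list[FitResult] = []
        for s in series:
            fits.append(estimate_km_vmax(s, on_complete="drop"))
        write_fit_table(fits, outdir / "fit_table.csv", e0=cfg.enzyme_load_g_per_L)
        logger.info("fitted %d series", len(fits))
        record("fit", "ok", ["fit_table.csv"])

        # -- stage 3: scaling ----------------------------------------------
        bt = cfg.bead_transport()
        rows = []
        groups: dict[float, object] = {}
        fit_by_s0: dict[float, FitResult] = {}
        for f in fits:
            fit_by_s0.setdefault(f.s0, f)
        for f in fit_by_s0.values():
            k_hat = MMKinetics(km=f.km_hat, vmax=f.vmax_hat)
            g = make_groups(bt, k_hat, f.s0)
            groups[f.s0] = g
            rows.append([f.s0, g.phi, g.beta, g.lam, g.tau_scale])
        pd.DataFrame(
            rows, columns=["S0_g_per_L", "phi", "beta", "lambda", "tau_scale_min"]
        ).to_csv(outdir / "groups.csv", index=False, float_format="%.12g")
        record("scale", "ok", ["groups.csv"])

        # -- stage 4: steady bead solves ------------------------------------
        mesh = AxiMesh.build(cfg.mesh_n)
        eff_rows = []
        field_files = []
        for f in fit_by_s0.values():
            g = groups[f.s0]
            fld = steady_axisymmetric(g.phi, g.beta, mesh=mesh)
            name = f"field_s0_{_s0_tag(f.s0)}.csv"
            write_field_csv(fld, outdir / name)
            field_files.append(name)
            eff = effectiveness_factor(fld)
            eff_rows.append([f.s0, g.phi, g.beta, eff.eta, eff.center_concentration])
            logger.info(
                "steady solve S0=%g: phi=%.4g beta=%.4g eta=%.4g",
                f.s0, g.phi, g.beta, eff.eta,
            )
        pd.DataFrame(
            eff_rows,
            columns=["S0_g_per_L", "phi", "beta", "eta", "center_Cs"],
        ).to_csv(outdir / "effectiveness.csv", index=False, float_format="%.12g")
        record("steady", "ok", field_files + ["effectiveness.csv"])

        # -- stage 5: optional transient ------------------------------------
        if cfg.transient:
            g = groups[fits[0].s0]
            snaps = transient_solve(
                g.phi, g.beta, lam=cfg.lam, tau_end=cfg.tau_end,
                mesh=mesh, n_snapshots=cfg.n_snapshots,
            )
            t_files = []
            for snap in snaps:
                tag = f"{snap.tau:.4g}".replace(".", "p")
                name = f"transient_tau_{tag}.csv"
                write_field_csv(snap, outdir / name)
                t_files.append(name)
            record("transient", "ok", t_files)
    except Exception as exc:
        stage_names = {s["name"] for s in manifest["stages"]}
        order = ["data", "fit", "scale", "steady", "transient"]
        failed = next(s for s in order if s not in stage_names)
        logger.error("stage %s failed: %s", failed, exc)
        record(failed, f"failed: {exc}", [])
        raise
    finally:
        root.removeHandler(log_file)
        log_file.close()
    return manifest
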