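"""Configured, logged, reproducible runs: generate -> fit -> scale -> simulate.

A run is described by a small YAML configuration with a mandatory seed;
``run_all`` executes the configured stages in dependency order, writes
delimited-text artifacts plus one machine-readable JSON report into the
output directory, and never keeps hidden state: every output is
re-derivable from config + seed.

Stages (each optional, selected by the presence of its config section):

* ``spectra``   — generate (or load) a spectrum, convert to
  susceptibility if needed, fit the Cole-Cole model per q, then derive
  the tau ~ q^-n exponent, beta = 2/n, the band-averaged alpha, and the
  bulk-like water fraction when a hydration level is given.
* ``trajectories`` — generate (or load) particle trajectories, fit the
  MSD exponent, and extract residence-time statistics (per hydration
  layer for layered runs).
* ``rj``        — the coarse-grained random-jump simulation, driven
  either by a parametric waiting model or by the residence-time
  distribution extracted from the trajectory stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ctrw import RJConfig, WaitingTimeModel, simulate_rj
from .residence import (
    layer_residence_distributions,
    residence_distribution,
    residence_times,
    second_moment,
)
from .scaling import (
    DEFAULT_BOUND_WATER,
    DEFAULT_MSD_WINDOW,
    DEFAULT_Q_BAND,
    average_alpha,
    bulk_like_fraction,
    compute_msd,
    fit_msd_exponent,
    fit_power_law_tau_q,
)
from .spectra import (
    STRUCTURE_FACTOR,
    SUSCEPTIBILITY,
    fit_cole_cole,
    fits_to_frame,
    read_spectrum,
    to_susceptibility,
    write_spectrum,
)
from .synthetic import (
    SpectraSpec,
    gen_cole_cole_spectra,
    gen_ctrw_trajectories,
    gen_layered_trajectories,
)
from .trajectories import read_trajectory, write_trajectory

__all__ = ["RunConfig", "RunReport", "validate_config", "serialize_config", "run_all"]

log = logging.getLogger("hydrosub")

_MODEL_KEYS = {"kind", "mean", "tail_exponent", "t_min"}
_SPECTRA_KEYS = {
    "path", "energy_units", "q_values", "taus", "tau0", "n_exponent",
    "alpha", "chi0", "n_freq", "freq_decades", "noise_level", "output_kind",
}
_TRAJ_KEYS = {
    "path", "kind", "model", "layer_models", "step_length", "n_particles",
    "t_max", "dt", "dims", "z_max", "write",
}
_RJ_KEYS = {
    "model", "use_residence", "step_length", "n_particles", "t_max",
}
_TOP_KEYS = {
    "seed", "outdir", "temperature", "q_band", "msd_window",
    "displacement_threshold", "layer_thickness", "bound_water",
    "hydration_level", "spectra", "trajectories", "rj",
}


@dataclass
class RunConfig:
    """Validated, defaulted run configuration."""

    seed: int
    outdir: str = "hydrosub_out"
    temperature: float = 280.0
    q_band: tuple[float, float] = DEFAULT_Q_BAND
    msd_window: tuple[float, float] = DEFAULT_MSD_WINDOW
    displacement_threshold: float = 3.5
    layer_thickness: float = 3.5
    bound_water: float = DEFAULT_BOUND_WATER
    hydration_level: float | None = None
    spectra: dict | None = None
    trajectories: dict | None = None
    rj: dict | None = None


@dataclass
class RunReport:
    """Everything one run computed, plus provenance."""

    results: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self, **kwargs) -> str:
        def _coerce(obj):
            if isinstance(obj, np.generic):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not JSON-serializable: {type(obj)}")

        return json.dumps(
            asdict(self), indent=2, sort_keys=True, default=_coerce, **kwargs
        )


class ConfigError(ValueError):
    """Raised when a run configuration is malformed."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    _require(not unknown, f"unknown keys in {where}: {sorted(unknown)}")


def _check_model(raw: dict, where: str) -> dict:
    _require(isinstance(raw, dict), f"{where} must be a mapping")
    _check_keys(raw, _MODEL_KEYS, where)
    WaitingTimeModel(**raw)  # raises on invalid parameters
    return dict(raw)


def _pair(raw, name: str) -> tuple[float, float]:
    _require(
        isinstance(raw, (list, tuple)) and len(raw) == 2 and raw[0] < raw[1],
        f"{name} must be an increasing [lo, hi] pair",
    )
    return (float(raw[0]), float(raw[1]))


def validate_config(source: str | dict | Path) -> RunConfig:
    """Parse and validate a configuration (YAML text, path, or mapping).

    Unknown keys are rejected; defaults are filled; the seed is mandatory
    (every stochastic stage derives its substream from it).  Numbers are
    checked against the same domain rules the library enforces, so a bad
    config fails here rather than mid-run.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml"))
    ):
        source = Path(source).read_text()
    raw = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    _require(isinstance(raw, dict), "configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "configuration")
    _require("seed" in raw, "seed is mandatory (stochastic stages must be reproducible)")
    seed = raw["seed"]
    _require(isinstance(seed, int) and not isinstance(seed, bool), "seed must be an integer")

    cfg = RunConfig(seed=seed)
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    if "temperature" in raw:
        cfg.temperature = float(raw["temperature"])
        _require(cfg.temperature > 0, "temperature must be positive")
    if "q_band" in raw:
        cfg.q_band = _pair(raw["q_band"], "q_band")
    if "msd_window" in raw:
        cfg.msd_window = _pair(raw["msd_window"], "msd_window")
    for key in ("displacement_threshold", "layer_thickness"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
            _require(getattr(cfg, key) > 0, f"{key} must be positive")
    if "bound_water" in raw:
        cfg.bound_water = float(raw["bound_water"])
        _require(cfg.bound_water >= 0, "bound_water must be non-negative")
    if "hydration_level" in raw and raw["hydration_level"] is not None:
        cfg.hydration_level = float(raw["hydration_level"])
        _require(cfg.hydration_level > 0, "hydration_level must be positive")

    if raw.get("spectra") is not None:
        sec = raw["spectra"]
        _check_keys(sec, _SPECTRA_KEYS, "spectra")
        if "path" not in sec:
            _require("q_values" in sec, "spectra generation needs q_values")
            alpha = float(sec.get("alpha", 0.2))
            _require(0.0 <= alpha < 1.0, "spectra.alpha must lie in [0, 1)")
            _require(float(sec.get("chi0", 1.0)) > 0, "spectra.chi0 must be positive")
            _require(float(sec.get("noise_level", 0.0)) >= 0, "noise_level must be >= 0")
            if "taus" in sec:
                _require(
                    len(sec["taus"]) == len(sec["q_values"]),
                    "spectra.taus must match q_values in length",
                )
                _require(all(t > 0 for t in sec["taus"]), "taus must be positive")
            else:
                _require(
                    float(sec.get("tau0", 5.0)) > 0 and float(sec.get("n_exponent", 2.0)) > 0,
                    "tau0 and n_exponent must be positive",
                )
            kind = sec.get("output_kind", SUSCEPTIBILITY)
            _require(
                kind in (SUSCEPTIBILITY, STRUCTURE_FACTOR),
                "output_kind must be susceptibility or structure_factor",
            )
        cfg.spectra = dict(sec)

    if raw.get("trajectories") is not None:
        sec = raw["trajectories"]
        _check_keys(sec, _TRAJ_KEYS, "trajectories")
        if "path" not in sec:
            kind = sec.get("kind", "ctrw")
            _require(kind in ("ctrw", "layered"), "trajectories.kind must be ctrw or layered")
            if kind == "ctrw":
                _require("model" in sec, "ctrw trajectories need a waiting model")
                _check_model(sec["model"], "trajectories.model")
            else:
                _require(
                    isinstance(sec.get("layer_models"), list) and sec["layer_models"],
                    "layered trajectories need a non-empty layer_models list",
                )
                for i, m in enumerate(sec["layer_models"]):
                    _check_model(m, f"trajectories.layer_models[{i}]")
            for key in ("step_length", "t_max", "dt"):
                if key in sec:
                    _require(float(sec[key]) > 0, f"trajectories.{key} must be positive")
        cfg.trajectories = dict(sec)

    if raw.get("rj") is not None:
        sec = raw["rj"]
        _check_keys(sec, _RJ_KEYS, "rj")
        if sec.get("model") is not None:
            _check_model(sec["model"], "rj.model")
        else:
            _require(
                bool(sec.get("use_residence", False)),
                "rj stage needs a model or use_residence: true",
            )
        cfg.rj = dict(sec)

    return cfg


def serialize_config(cfg: RunConfig) -> str:
    """Canonical YAML form of a validated configuration."""
    d = asdict(cfg)
    d["q_band"] = list(d["q_band"])
    d["msd_window"] = list(d["msd_window"])
    d = {k: v for k, v in d.items() if v is not None}
    return yaml.safe_dump(d, sort_keys=True)


def _build_spectrum(cfg: RunConfig):
    sec = cfg.spectra
    if "path" in sec:
        return read_spectrum(
            sec["path"],
            temperature=cfg.temperature,
            kind=sec.get("output_kind", SUSCEPTIBILITY),
            energy_units=sec.get("energy_units", "THz"),
        )
    q = np.asarray(sec["q_values"], dtype=float)
    if "taus" in sec:
        taus = np.asarray(sec["taus"], dtype=float)
    else:
        taus = float(sec.get("tau0", 5.0)) * q ** (-float(sec.get("n_exponent", 2.0)))
    alpha = float(sec.get("alpha", 0.2))
    chi0 = float(sec.get("chi0", 1.0))
    n_freq = int(sec.get("n_freq", 200))
    decades = float(sec.get("freq_decades", 3.0))
    nu_peaks = 1.0 / (2.0 * np.pi * taus)
    freqs = np.geomspace(
        nu_peaks.min() / 10**decades, nu_peaks.max() * 10**decades, n_freq
    )
    spec = SpectraSpec(
        q_values=q,
        taus=taus,
        alphas=np.full_like(q, alpha),
        chi0s=np.full_like(q, chi0),
        frequencies=freqs,
        noise_level=float(sec.get("noise_level", 0.0)),
        temperature=cfg.temperature,
        output_kind=sec.get("output_kind", SUSCEPTIBILITY),
        seed=cfg.seed,
    )
    return gen_cole_cole_spectra(spec)


def _build_trajectory(cfg: RunConfig):
    sec = cfg.trajectories
    if "path" in sec:
        return read_trajectory(sec["path"], dims=int(sec.get("dims", 3)))
    t_max = float(sec.get("t_max", 2000.0))
    dt = float(sec.get("dt", 0.25))
    obs = np.arange(0.0, t_max + dt / 2, dt)
    if sec.get("kind", "ctrw") == "layered":
        models = [WaitingTimeModel(**m) for m in sec["layer_models"]]
        return gen_layered_trajectories(
            models,
            layer_thickness=cfg.layer_thickness,
            n_particles=int(sec.get("n_particles", 400)),
            t_max=t_max,
            seed=cfg.seed + 1,
            step_length=float(sec.get("step_length", 3.5)),
            observation_times=obs,
            z_max=sec.get("z_max"),
        )
    model = WaitingTimeModel(**sec["model"])
    return gen_ctrw_trajectories(
        model,
        step_length=float(sec.get("step_length", 3.5)),
        n_particles=int(sec.get("n_particles", 1000)),
        t_max=t_max,
        dims=int(sec.get("dims", 1)),
        seed=cfg.seed + 1,
        observation_times=obs,
    )


def run_all(cfg: RunConfig, quiet: bool = False) -> RunReport:
    """Execute all configured stages and write artifacts + JSON report.

    A stage failure is recorded in ``report.failures`` and its dependents
    are skipped; the report is always written.  With the same config and
    seed the report is byte-identical apart from the timestamp.
    """
    if not quiet and not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    config_text = serialize_config(cfg)
    # hash the scientific configuration only: where outputs land does not
    # change what is computed
    hashed = "\n".join(
        line for line in config_text.splitlines() if not line.startswith("outdir:")
    )
    report.provenance = {
        "config_sha256": hashlib.sha256(hashed.encode()).hexdigest(),
        "package_version": __version__,
        "seed": cfg.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "config.yaml").write_text(config_text)

    residence_dist = None

    if cfg.spectra is not None:
        try:
            log.info("spectra stage: temperature=%g K", cfg.temperature)
            grid = _build_spectrum(cfg)
            write_spectrum(grid, outdir / "spectrum.tsv")
            if grid.kind == STRUCTURE_FACTOR:
                grid = to_susceptibility(grid)
                write_spectrum(grid, outdir / "susceptibility.tsv")
            fits = [fit_cole_cole(grid, i) for i in range(grid.n_q)]
            frame = fits_to_frame(fits)
            frame.to_csv(outdir / "cole_cole_fits.tsv", sep="\t", index=False)
            scal = fit_power_law_tau_q(
                list(zip(frame["q"], frame["tau_ps"])), q_range=cfg.q_band
            )
            alpha_bar = average_alpha(fits, q_range=cfg.q_band)
            report.results["spectra"] = {
                "fits": frame.to_dict(orient="records"),
                "n": scal.n,
                "beta_from_n": scal.beta,
                "alpha_bar": alpha_bar,
                "r_squared": scal.r_squared,
            }
            if cfg.hydration_level is not None:
                report.results["spectra"]["bulk_like_fraction"] = bulk_like_fraction(
                    cfg.hydration_level, cfg.bound_water
                )
            report.artifacts["cole_cole_fits"] = "cole_cole_fits.tsv"
            log.info("spectra stage: n=%.3f beta=%.3f alpha_bar=%.3f",
                     scal.n, scal.beta, alpha_bar)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.error("spectra stage failed: %s", exc)
            report.failures["spectra"] = str(exc)

    traj = None
    if cfg.trajectories is not None:
        try:
            log.info("trajectory stage")
            traj = _build_trajectory(cfg)
            if cfg.trajectories.get("write", False):
                write_trajectory(traj, outdir / "trajectory.tsv")
                report.artifacts["trajectory"] = "trajectory.tsv"
            layered = cfg.trajectories.get("kind") == "layered"
            msd_traj = traj.lateral() if layered and traj.dims == 3 else traj
            msd = compute_msd(msd_traj, origin_stride=0)
            beta_msd = fit_msd_exponent(msd, cfg.msd_window)
            rts = residence_times(traj, threshold=cfg.displacement_threshold)
            residence_dist = residence_distribution(rts)
            mean, sq_dev = second_moment(rts)
            residence_dist.to_frame().to_csv(
                outdir / "residence_distribution.tsv", sep="\t", index=False
            )
            report.artifacts["residence_distribution"] = "residence_distribution.tsv"
            result = {
                "beta_msd": beta_msd,
                "residence_mean": mean,
                "residence_squared_deviation": sq_dev,
                "residence_samples": rts.n,
                "censored_fraction": rts.censored_fraction,
            }
            if layered:
                per_layer = layer_residence_distributions(
                    traj,
                    threshold=cfg.displacement_threshold,
                    layer_thickness=cfg.layer_thickness,
                )
                result["layers"] = {
                    str(layer): {"count": d.count, "mean": d.mean()}
                    for layer, d in per_layer.items()
                }
            report.results["trajectories"] = result
            log.info("trajectory stage: beta_msd=%.3f, %d residence samples",
                     beta_msd, rts.n)
        except Exception as exc:  # noqa: BLE001
            log.error("trajectory stage failed: %s", exc)
            report.failures["trajectories"] = str(exc)

    if cfg.rj is not None:
        sec = cfg.rj
        skip = False
        if sec.get("use_residence", False):
            if residence_dist is None:
                msg = "rj.use_residence set but no residence distribution available"
                if "trajectories" in report.failures or cfg.trajectories is not None:
                    msg += " (trajectory stage failed)"
                log.error("rj stage skipped: %s", msg)
                report.failures["rj"] = msg
                skip = True
            else:
                model = WaitingTimeModel.from_distribution(residence_dist)
        else:
            model = WaitingTimeModel(**sec["model"])
        if not skip:
            try:
                log.info("rj stage: %s waits", model.kind)
                rj_cfg = RJConfig(
                    model=model,
                    step_length=float(sec.get("step_length", 3.5)),
                    n_particles=int(sec.get("n_particles", 5000)),
                    t_max=float(sec.get("t_max", 2000.0)),
                    fit_window=cfg.msd_window,
                    seed=cfg.seed + 2,
                )
                res = simulate_rj(rj_cfg)
                np.savetxt(
                    outdir / "rj_msd.tsv",
                    np.column_stack([res.msd.lags, res.msd.msd]),
                    delimiter="\t",
                    header="lag_ps\tmsd_A2",
                    comments="",
                )
                report.artifacts["rj_msd"] = "rj_msd.tsv"
                report.results["rj"] = {
                    "beta": res.beta,
                    "jumps_mean": res.jumps_mean,
                    "degenerate": res.degenerate,
                    "waiting_model": model.kind,
                }
                log.info("rj stage: beta=%.3f", res.beta)
            except Exception as exc:  # noqa: BLE001
                log.error("rj stage failed: %s", exc)
                report.failures["rj"] = str(exc)

    (outdir / "report.json").write_text(report.to_json())
    return report
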