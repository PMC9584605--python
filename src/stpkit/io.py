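"""Plain-text file formats, configuration validation and the pipeline.

All tabular data are comma-separated text with unit-bearing headers
(``ap_time_s``, ``amplitude_nA``, ``time_ms`` ...); model parameters travel
as JSON documents with top-level keys ``model``, ``params``, ``calcium``
and ``pr_dynamics`` whose fields mirror the parameter dataclasses exactly.
Every pipeline artifact gets a provenance sidecar (config hash, seed,
package version) so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .models import (CalciumDynamics, EPSCTrain, PrDynamics,
                     SinglePoolParams, StimulusProtocol, TwoStepParams)

__all__ = [
    "ConfigError",
    "read_train", "write_train",
    "read_trace", "write_trace",
    "read_params", "write_params",
    "validate_config", "run_pipeline",
]

logger = logging.getLogger("stpkit")

TRAIN_COLUMNS = ("stimulus_index", "ap_time_s", "amplitude_nA", "m_j", "pr_j")
TRACE_COLUMNS = ("time_ms", "current_nA")


class ConfigError(ValueError):
    """Raised for malformed configuration or data files."""


# ---------------------------------------------------------------------------
# EPSC train tables
# ---------------------------------------------------------------------------

def write_train(path: Union[str, Path], train: EPSCTrain) -> None:
    """Write an EPSC train as a CSV table with a unit-bearing header."""
    n = len(train)
    df = pd.DataFrame({
        "stimulus_index": np.arange(1, n + 1),
        "ap_time_s": train.ap_times,
        "amplitude_nA": train.amplitudes,
        "m_j": (train.quantal_contents if train.quantal_contents is not None
                else np.full(n, np.nan)),
        "pr_j": (train.pr_per_ap if train.pr_per_ap is not None
                 else np.full(n, np.nan)),
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_train(path: Union[str, Path]) -> EPSCTrain:
    """Read an EPSC train table (columns as written by :func:`write_train`)."""
    df = pd.read_csv(path)
    missing = {"ap_time_s", "amplitude_nA"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required columns {sorted(missing)}")
    m = df["m_j"].to_numpy() if "m_j" in df else None
    pr = df["pr_j"].to_numpy() if "pr_j" in df else None
    if m is not None and np.all(np.isnan(m)):
        m = None
    if pr is not None and np.all(np.isnan(pr)):
        pr = None
    return EPSCTrain(ap_times=df["ap_time_s"].to_numpy(),
                     amplitudes=df["amplitude_nA"].to_numpy(),
                     quantal_contents=m, pr_per_ap=pr,
                     mode="experimental")


# ---------------------------------------------------------------------------
# current traces
# ---------------------------------------------------------------------------

def write_trace(path: Union[str, Path], time_ms: np.ndarray,
                current_nA: np.ndarray) -> None:
    pd.DataFrame({"time_ms": time_ms, "current_nA": current_nA}).to_csv(
        path, index=False, float_format="%.12g")


def read_trace(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    """Read a two-column trace; rejects non-uniform sampling."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required columns {sorted(missing)}")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size > 2:
        dt = np.diff(t)
        if np.max(np.abs(dt - dt[0])) > 1e-6 * abs(dt[0]):
            raise ConfigError(f"{path}: sampling is not uniform")
    return t, df["current_nA"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# model parameter documents
# ---------------------------------------------------------------------------

_PARAM_CLS = {"single_pool": SinglePoolParams, "two_step": TwoStepParams}


def write_params(path: Union[str, Path], model: str, params,
                 calcium: CalciumDynamics, pr_dynamics: PrDynamics) -> None:
    doc = {
        "model": model,
        "params": dataclasses.asdict(params),
        "calcium": dataclasses.asdict(calcium),
        "pr_dynamics": dataclasses.asdict(pr_dynamics),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_params(path: Union[str, Path]):
    """Read a model-parameter JSON document.

    Returns ``(model, params, calcium, pr_dynamics)``; unknown keys and
    field names are rejected.
    """
    doc = json.loads(Path(path).read_text())
    extra = set(doc) - {"model", "params", "calcium", "pr_dynamics"}
    if extra:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(extra)}")
    model = doc.get("model")
    if model not in _PARAM_CLS:
        raise ConfigError(f"{path}: model must be one of {sorted(_PARAM_CLS)}")
    try:
        params = _PARAM_CLS[model](**doc.get("params", {}))
        calcium = CalciumDynamics(**doc.get("calcium", {}))
        pr_dyn = PrDynamics(**doc.get("pr_dynamics", {}))
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return model, params, calcium, pr_dyn


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_STAGES = ("generate", "simulate", "analyze", "recover", "fit")
_TOP_KEYS = set(_STAGES) | {"seed", "outdir", "log_level"}


def validate_config(config: dict) -> dict:
    """Validate a pipeline configuration dictionary.

    Required: integer ``seed`` and at least one stage block.  Unknown
    top-level keys are rejected.  Returns the config with defaults filled.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    extra = set(config) - _TOP_KEYS
    if extra:
        raise ConfigError(f"unknown config keys {sorted(extra)}")
    if not isinstance(config.get("seed"), int):
        raise ConfigError("config requires an integer 'seed'")
    if not any(s in config for s in _STAGES):
        raise ConfigError(f"config needs at least one stage of {_STAGES}")
    cfg = dict(config)
    cfg.setdefault("outdir", ".")
    cfg.setdefault("log_level", "INFO")
    return cfg


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar(path: Path, config: dict, seed: int) -> None:
    meta = {"config_hash": _config_hash(config), "seed": seed,
            "stpkit_version": __version__}
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _resolve_model(block: dict):
    """(params, calcium, pr_dynamics) from a stage block."""
    from .defaults import default_calibration

    if "params_file" in block:
        _, params, ca, pr = read_params(block["params_file"])
        return params, ca, pr
    return default_calibration(block.get("model", "single_pool"),
                               block.get("condition", "control"))


def run_pipeline(config: dict, outdir: Optional[Union[str, Path]] = None) -> dict:
    """Run the configured stages; returns ``{artifact name: path}``.

    Stage outputs already present in ``outdir`` are reused (partial-rerun
    resume); every written artifact carries a provenance sidecar.  All
    randomness derives from the config seed.
    """
    cfg = validate_config(config)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg["log_level"], logging.INFO))
    seed = cfg["seed"]
    artifacts = {}

    def fresh(name: str) -> Optional[Path]:
        p = out / name
        artifacts[name] = p
        if p.exists():
            logger.info("reusing existing artifact %s", p)
            return None
        return p

    if "generate" in cfg:
        from .synthetic import BiExpKernel, gen_mepsc_trace

        g = cfg["generate"]
        p = fresh(g.get("out", "mepsc_trace.csv"))
        if p is not None:
            kernel = BiExpKernel(**g.get("kernel", {}))
            t, tr, truth = gen_mepsc_trace(
                duration=g.get("duration_s", 10.0),
                rate=g.get("rate_hz", 10.0), kernel=kernel,
                noise_sd=g.get("noise_sd", 0.005), seed=seed)
            write_trace(p, t, tr)
            truth_out = {k: (v.tolist() if isinstance(v, np.ndarray)
                             else dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                             else v) for k, v in truth.items()}
            p.with_suffix(".truth.json").write_text(
                json.dumps(truth_out, indent=2, sort_keys=True) + "\n")
            _sidecar(p, cfg, seed)

    if "simulate" in cfg:
        from .models import simulate as _simulate
        from .synthetic import gen_regular_protocol

        s = cfg["simulate"]
        p = fresh(s.get("out", "train.csv"))
        if p is not None:
            params, ca, pr = _resolve_model(s)
            proto = gen_regular_protocol(s.get("n_stimuli", 50),
                                         s.get("rate_hz", 500.0))
            train, _ = _simulate(proto, params, ca, pr,
                                 mode=s.get("mode", "deterministic"),
                                 seed=seed)
            write_train(p, train)
            _sidecar(p, cfg, seed)

    if "analyze" in cfg:
        from .quantal import eq_estimate, nprf_estimate, smn_estimate, train_metrics

        a = cfg["analyze"]
        p = fresh(a.get("out", "estimates.json"))
        if p is not None:
            train_path = a.get("train") or str(artifacts.get("train.csv", ""))
            if not train_path or not Path(train_path).exists():
                raise ConfigError("analyze stage: no train file available")
            train = read_train(train_path)
            logger.info("analyze: EQ n_points=%d, SMN corrected=%s ss_window=%d",
                        a.get("eq_points", 4), a.get("smn_corrected", True),
                        a.get("ss_window", 10))
            results = {}
            m = train_metrics(train, ss_window=a.get("ss_window", 10))
            results["metrics"] = {
                "ppr": m.ppr, "epsc1_nA": m.epsc1, "epsc_ss_nA": m.epsc_ss,
                "depression_ratio": m.depression_ratio}
            for name, call in (
                    ("eq", lambda: eq_estimate(train, a.get("eq_points", 4))),
                    ("smn", lambda: smn_estimate(
                        train, ss_window=a.get("ss_window", 10),
                        corrected=a.get("smn_corrected", True))),
                    ("nprf", lambda: nprf_estimate(train))):
                try:
                    est = call()
                    results[name] = {"rrp": est.rrp, "pr": est.pr,
                                     "replenishment": est.replenishment}
                except Exception as exc:
                    results[name] = {"error": str(exc)}
            p.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
            _sidecar(p, cfg, seed)

    if "recover" in cfg:
        from .models import recovery_curve
        from .recovery import fit_recovery
        from .synthetic import gen_regular_protocol, log_spaced_intervals

        r = cfg["recover"]
        p = fresh(r.get("out", "recovery.csv"))
        if p is not None:
            params, ca, pr = _resolve_model(r)
            cond = gen_regular_protocol(r.get("cond_n", 50),
                                        r.get("cond_rate_hz", 500.0))
            test = gen_regular_protocol(r.get("test_n", 1),
                                        r.get("test_rate_hz", 500.0))
            intervals = np.asarray(r.get(
                "intervals_s", log_spaced_intervals().tolist()))
            ds = recovery_curve(params, ca, pr, cond, intervals, test,
                                seed=seed)
            frac = ds.fractional()
            pd.DataFrame({"interval_s": ds.intervals, "value": frac}).to_csv(
                p, index=False, float_format="%.12g")
            fit_res = fit_recovery(ds.intervals, frac,
                                   force_model=r.get("force_model", "auto"))
            p.with_suffix(".fit.json").write_text(json.dumps(
                {k: v for k, v in dataclasses.asdict(fit_res).items()},
                indent=2, sort_keys=True, default=float) + "\n")
            _sidecar(p, cfg, seed)

    if "fit" in cfg:
        from .calibration import fit as _fit
        from .calibration import CalibrationProblem
        from .synthetic import gen_regular_protocol

        f = cfg["fit"]
        p = fresh(f.get("out", "calibration.json"))
        if p is not None:
            base = {}
            datasets = {}
            for cond, block in f["conditions"].items():
                base[cond] = _resolve_model(block)
                datasets[cond] = {}
                for key in ("train_50hz", "train_500hz"):
                    if key in block:
                        tr = read_train(block[key])
                        proto = StimulusProtocol(tr.ap_times)
                        datasets[cond][key] = (proto, tr.amplitudes)
                if "recovery" in block:
                    rb = block["recovery"]
                    tbl = pd.read_csv(rb["table"])
                    cond_proto = gen_regular_protocol(
                        rb.get("cond_n", 50), rb.get("cond_rate_hz", 500.0))
                    test = gen_regular_protocol(1, 500.0)
                    datasets[cond]["recovery"] = (
                        cond_proto, test, tbl["interval_s"].to_numpy(),
                        tbl["value"].to_numpy())
            problem = CalibrationProblem(
                model_kind=f.get("model", "single_pool"), base=base,
                datasets=datasets, free_params=f.get("free_params", []),
                shared_params=f.get("shared_params", []),
                bounds={k: tuple(v) for k, v in f.get("bounds", {}).items()},
                weights=f.get("weights", {}))
            result = _fit(problem, n_starts=f.get("n_starts", 8), seed=seed,
                          maxfev=f.get("maxfev", 400))
            doc = {"fitted": result.fitted, "loss": result.loss,
                   "converged": result.converged, "at_bound": result.at_bound,
                   "per_dataset_loss": result.per_dataset_loss,
                   "n_starts": result.n_starts, "seed": result.seed}
            p.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
            _sidecar(p, cfg, seed)

    return artifacts
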