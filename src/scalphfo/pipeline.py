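"""End-to-end orchestration: simulate/load -> detect -> features ->
cluster -> stats, with reproducibility bookkeeping.

A single master seed drives every stochastic stage; per-stage seeds are
derived by hashing (master seed, stage name) so streams cannot couple
accidentally.  Each run writes a manifest (config hash, derived seeds,
library versions, per-stage row counts) sufficient to reproduce and audit
the run; manifests for identical configs are identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import fit_phenotypes
from .core import EPOCH_LABELS, SPIKE_RIPPLE, TEN_TWENTY_CHANNELS, UNASSIGNED
from .detect import DetectorConfig, run_detector
from .features import extract_features
from .stats import (
    StatsError,
    build_contingency,
    chi_square_test,
    make_reports,
    multinomial_logit,
)
from .synth import read_epoch_annotations, read_spike_annotations


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def derive_seed(master: int, name: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{master}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one input source must be set: an EDF recording (with spike
    and epoch annotation CSVs) or a ready-made feature table CSV.
    """

    out_dir: str = "hfo_out"
    edf_path: str | None = None
    spikes_csv: str | None = None
    epochs_csv: str | None = None
    features_csv: str | None = None
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    k: int | None = None               # None -> elbow selection
    k_max: int = 8
    n_restarts: int = 300
    age_adjust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [self.edf_path is not None, self.features_csv is not None]
        if sum(sources) != 1:
            raise PipelineError("exactly one input source (EDF or feature CSV) required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise PipelineError("config must set an explicit seed")
        det = raw.pop("detector", {})
        if det.get("band") is not None:
            det["band"] = tuple(det["band"])
        return cls(detector=DetectorConfig(**det), **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Pre-flight checks; returns a list of machine-readable failures."""
    failures: list[dict] = []
    if config.edf_path is not None:
        from .edf import read_edf

        try:
            rec = read_edf(config.edf_path)
        except Exception as exc:  # unreadable file is a hard failure
            return [{"code": "edf_unreadable", "message": str(exc)}]
        if rec.sfreq < 1000.0:
            failures.append(
                {
                    "code": "sampling_rate",
                    "message": f"sampling rate {rec.sfreq:g} Hz below the "
                    "1000 Hz required for ripple-band analysis",
                }
            )
        unknown = [c for c in rec.channels if c not in TEN_TWENTY_CHANNELS]
        if unknown:
            failures.append(
                {"code": "channel_labels",
                 "message": f"non-10-20 channel labels: {unknown}"}
            )
        if config.epochs_csv:
            from .core import AnnotationError, ICTAL_ACTIVE, check_epochs_disjoint

            try:
                epochs = read_epoch_annotations(config.epochs_csv)
                check_epochs_disjoint(epochs)
            except (AnnotationError, ValueError) as exc:
                failures.append({"code": "epochs", "message": str(exc)})
            else:
                for ep in epochs:
                    if ep.label == ICTAL_ACTIVE and ep.offset - ep.onset < 3.0:
                        failures.append(
                            {"code": "ictal_duration",
                             "message": f"ictal epoch [{ep.onset}, {ep.offset}) "
                             "shorter than 3 s"}
                        )
    return failures


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write events/features/clusters/report files.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "seeds": {"cluster": derive_seed(config.seed, "cluster")},
        "versions": _versions(),
        "stages": {},
    }

    if config.features_csv is not None:
        manifest["stages"]["detect"] = {"status": "skipped"}
        manifest["stages"]["features"] = {"status": "skipped"}
        features = pd.read_csv(config.features_csv)
    else:
        features = _detect_and_extract(config, out, manifest)

    age = features["age"].to_numpy(float) if (
        config.age_adjust and "age" in features.columns
    ) else None

    model, labelled, excluded = _cluster_stage(config, features, manifest)
    labelled.to_csv(out / "clusters.csv", index=False)
    (out / "model.json").write_text(
        json.dumps(
            {
                "k": model.k,
                "centroids_standardized": model.centroids.tolist(),
                "centroids_raw": model.centroids_raw.tolist(),
                "total_wss": model.total_wss,
                "wss_curve": {str(k): v for k, v in model.wss_curve.items()},
                "n_restarts": model.n_restarts,
                "seed": model.seed,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    _stats_stage(labelled, age, out, manifest)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


@_stage("detect")
def _detect_and_extract(config: PipelineConfig, out: Path, manifest: dict):
    from .edf import read_edf

    recording = read_edf(config.edf_path, min_sfreq=1000.0)
    spikes = read_spike_annotations(config.spikes_csv) if config.spikes_csv else []
    epochs = read_epoch_annotations(config.epochs_csv) if config.epochs_csv else []
    events, filtered = run_detector(recording, spikes, epochs, config.detector)
    pd.DataFrame(
        [
            {"channel": ev.channel, "onset_s": ev.onset, "offset_s": ev.offset,
             "kind": ev.kind, "epoch": ev.epoch, "peak_envelope": ev.peak_envelope}
            for ev in events
        ]
    ).to_csv(out / "events.csv", index=False)
    manifest["stages"]["detect"] = {
        "events": len(events),
        "spike_ripples": sum(1 for ev in events if ev.kind == SPIKE_RIPPLE),
    }
    features = extract_features(filtered, events, config.detector)
    # the analysis set: spike ripples inside an annotated epoch
    features = features[
        (features["kind"] == SPIKE_RIPPLE) & (features["epoch"] != UNASSIGNED)
    ].reset_index(drop=True)
    features.to_csv(out / "features.csv", index=False)
    manifest["stages"]["features"] = {"events": int(len(features))}
    return features


@_stage("cluster")
def _cluster_stage(config: PipelineConfig, features: pd.DataFrame, manifest: dict):
    model, labelled, excluded = fit_phenotypes(
        features,
        k=config.k,
        k_max=config.k_max,
        n_restarts=config.n_restarts,
        seed=derive_seed(config.seed, "cluster"),
    )
    manifest["stages"]["cluster"] = {
        "k": model.k,
        "events_in": int(len(features)),
        "outliers_excluded": int(len(excluded)),
        "cluster_sizes": model.cluster_sizes().tolist(),
        "total_wss": model.total_wss,
    }
    return model, labelled, excluded


@_stage("stats")
def _stats_stage(labelled: pd.DataFrame, age, out: Path, manifest: dict) -> None:
    have_epochs = "epoch" in labelled.columns and set(
        labelled["epoch"].dropna()
    ) <= set(EPOCH_LABELS) and labelled["epoch"].notna().all()
    if not have_epochs or labelled["epoch"].nunique() < 2:
        manifest["stages"]["stats"] = {"status": "skipped (need >=2 epochs)"}
        return
    table = build_contingency(labelled["cluster"], labelled["epoch"])
    chi2 = chi_square_test(table)
    try:
        fit = multinomial_logit(labelled["epoch"], labelled["cluster"])
    except (StatsError, np.linalg.LinAlgError):
        fit = None
    make_reports(table, fit, chi2, labelled, out, age=age)
    manifest["stages"]["stats"] = {
        "chi_square": round(chi2.statistic, 4),
        "df": chi2.df,
        "multinomial_converged": None if fit is None else fit.converged,
    }


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
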