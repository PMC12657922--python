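"""End-to-end orchestration: simulate -> preprocess -> encode -> stats.

Each stage writes its outputs under a run directory and records file
checksums in a manifest, so a finished run can be audited and an interrupted
one resumed.  Stages whose outputs already exist are skipped unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import EncodingConfig, average_over_electrodes, encode_layerwise
from .errors import LagLayerError, ValidationError
from .io import read_bundle, read_encoding, write_bundle, write_encoding
from .preprocessing import despike, rereference_car, highgamma_power, smooth_hamming
from .stats import lag_layer_analysis
from .synthetic import SyntheticConfig, generate_neural_dataset

__all__ = ["RunConfig", "run_pipeline", "StageFailure"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "encode", "stats")

_PREPROCESS_OPS = {
    "despike": despike,
    "car": rereference_car,
    "highgamma": highgamma_power,
    "smooth": smooth_hamming,
}


class StageFailure(LagLayerError):
    """A pipeline stage raised; carries the failing stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from scratch.

    The default preprocessing for synthetic data is despiking plus Hamming
    smoothing: the generated signal already emulates a smoothed power trace,
    so common-average referencing and the spectral high-gamma stage are
    reserved for raw voltage-like inputs and must be requested explicitly.
    """

    out_dir: str = "laglayer_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    encoding: EncodingConfig = field(
        default_factory=lambda: EncodingConfig(lag_min=-1000.0, lag_max=1000.0)
    )
    preprocess_steps: tuple = ("despike", "smooth")
    roi: str | None = None
    permutations: int = 10_000
    seed: int = 0
    force: bool = False
    p_alternative: str = "two-sided"

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "synthetic": self.synthetic.to_dict(),
            "encoding": self.encoding.to_dict(),
            "preprocess_steps": list(self.preprocess_steps),
            "roi": self.roi,
            "permutations": self.permutations,
            "seed": self.seed,
            "p_alternative": self.p_alternative,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "encoding" in d:
            d["encoding"] = EncodingConfig.from_dict(d["encoding"])
        if "preprocess_steps" in d:
            d["preprocess_steps"] = tuple(d["preprocess_steps"])
        d.pop("force", None)
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the four stages in order and return the run manifest.

    Stage outputs already on disk are reused unless ``config.force``; a stage
    failure aborts the run with the failing stage named while earlier outputs
    are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.synthetic.seed = int(config.seed)
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "stages": {},
    }

    raw_dir = out / "raw"
    prep_dir = out / "preprocessed"
    enc_path = out / "encoding.h5"
    stats_path = out / "stats.json"

    def record(stage: str, outputs: list, skipped: bool) -> None:
        manifest["stages"][stage] = {
            "skipped": skipped,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    # simulate
    try:
        raw_files = [raw_dir / "signal.h5", raw_dir / "events.csv", raw_dir / "meta.json"]
        if all(p.exists() for p in raw_files) and not config.force:
            record("simulate", raw_files, skipped=True)
        else:
            ds = generate_neural_dataset(config.synthetic)
            events = ds.events.assign_folds(config.encoding.n_folds)
            truth = {k: v for k, v in ds.truth.items() if k != "readouts"}
            write_bundle(raw_dir, events, ds.embeddings, ds.recording,
                         truth=truth, config=config.synthetic.to_dict())
            record("simulate", raw_files, skipped=False)
    except Exception as exc:  # noqa: BLE001 - named stage failure contract
        raise StageFailure("simulate", exc) from exc

    # preprocess
    try:
        prep_files = [prep_dir / "signal.h5", prep_dir / "events.csv",
                      prep_dir / "meta.json"]
        if all(p.exists() for p in prep_files) and not config.force:
            record("preprocess", prep_files, skipped=True)
        else:
            events, emb, rec, meta = read_bundle(raw_dir)
            for step in config.preprocess_steps:
                if step not in _PREPROCESS_OPS:
                    raise ValidationError(f"unknown preprocessing step {step!r}")
                rec = _PREPROCESS_OPS[step](rec)
            write_bundle(prep_dir, events, emb, rec,
                         truth=meta.get("truth"), config=meta.get("config"))
            record("preprocess", prep_files, skipped=False)
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure("preprocess", exc) from exc

    # encode
    try:
        if enc_path.exists() and not config.force:
            record("encode", [enc_path], skipped=True)
        else:
            events, emb, rec, _ = read_bundle(prep_dir)
            tensor = encode_layerwise(rec, events, emb, config.encoding)
            write_encoding(enc_path, tensor)
            record("encode", [enc_path], skipped=False)
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure("encode", exc) from exc

    # stats
    try:
        if stats_path.exists() and not config.force:
            record("stats", [stats_path], skipped=True)
        else:
            tensor = read_encoding(enc_path)
            mat = average_over_electrodes(tensor, config.roi)
            result = lag_layer_analysis(
                mat, tensor.lags, tensor.layer_ids,
                K=config.permutations, seed=config.seed,
                alternative=config.p_alternative,
            )
            payload = result.to_dict()
            payload["roi"] = config.roi
            payload["seed"] = int(config.seed)
            payload["permutations"] = int(config.permutations)
            stats_path.write_text(json.dumps(payload, indent=2))
            np.savetxt(
                out / "peak_lags.csv",
                np.column_stack([tensor.layer_ids, result.peak_lags]),
                delimiter=",", header="layer,peak_lag_ms", comments="",
            )
            record("stats", [stats_path], skipped=False)
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure("stats", exc) from exc

    manifest_blob = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest_blob)
    manifest["manifest_hash"] = hashlib.sha256(manifest_blob.encode()).hexdigest()
    return manifest
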