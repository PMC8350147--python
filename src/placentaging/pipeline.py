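"""End-to-end orchestration: phantom cohort -> relaxometry -> segmentation ->
mean T2* -> normative TLS-GP scoring.

Each stage is independently usable through the library (or the CLI), so real
NIfTI data can replace the phantom stage at any point; :func:`run_pipeline`
wires them together for a fully synthetic closed-loop run and emits a JSON
manifest recording configuration, seeds, per-subject results and content
hashes, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from placentaging.phantom import CohortSpec, PhantomSpec, simulate_cohort, simulate_multiecho_volume
from placentaging.relaxometry import fit_volume, masked_mean_t2s
from placentaging.segmentation import UNetSegmenter, make_folds
from placentaging.tlsgp import TLSGPNormativeModel
from placentaging.evaluation import dice

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    """Configuration of a closed-loop phantom run."""

    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n_low_risk=8, n_high_risk=2))
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seg_params: dict = field(default_factory=dict)  # UNetSegmenter overrides
    sigma_eps: float = 1.3
    sigma_delta: float = 8.7
    n_folds: int = 5
    test_fold: int = 0
    n_mc_samples: int = 10000
    seed: int = 0
    out_dir: str | None = None


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline and return the manifest dict.

    Stages: simulate cohort and per-subject multi-echo phantoms; fit T2* maps;
    hold out one stratified fold, train the U-net on the rest; predict masks
    for all subjects; compute mean T2* from the predicted masks; fit the
    TLS-GP normative model on low-risk subjects and score everyone (Z and
    accelerated-aging probability). Deterministic given the seeds in
    ``config``; rerunning yields identical manifest hashes.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    manifest: dict = {"config": _config_dict(config), "stage_seeds": seeds.tolist()}

    try:
        cohort = simulate_cohort(config.cohort)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    manifest["cohort_hash"] = hashlib.sha256(
        cohort.to_csv(index=False).encode()
    ).hexdigest()[:16]

    volumes, masks, maps = {}, {}, {}
    try:
        for i, row in cohort.iterrows():
            vol, mask = simulate_multiecho_volume(row, config.phantom, seed=int(seeds[0]) + i)
            volumes[row.subject_id] = vol
            masks[row.subject_id] = mask
    except Exception as e:  # noqa: BLE001
        raise StageError("phantom", str(e)) from e

    try:
        for sid, vol in volumes.items():
            maps[sid] = fit_volume(vol)
    except Exception as e:  # noqa: BLE001
        raise StageError("relaxometry", str(e)) from e
    manifest["t2s_map_hashes"] = {sid: _sha256(m.t2s) for sid, m in maps.items()}

    try:
        folds = make_folds(cohort, config.n_folds, seed=int(seeds[1]))
        test_ids = [s for s, f in folds.items() if f == config.test_fold]
        train_ids = [s for s in cohort.subject_id if s not in test_ids]
        seg = UNetSegmenter(seed=int(seeds[2]), **config.seg_params)
        seg.fit([maps[s].t2s for s in train_ids], [masks[s] for s in train_ids])
        pred_masks = {sid: seg.predict(maps[sid].t2s) for sid in cohort.subject_id}
    except Exception as e:  # noqa: BLE001
        raise StageError("segmentation", str(e)) from e

    records = []
    try:
        for _, row in cohort.iterrows():
            sid = row.subject_id
            mean_t2s = masked_mean_t2s(maps[sid], pred_masks[sid])
            rec = {
                "subject_id": sid,
                "ga_weeks": float(row.ga_weeks),
                "group": row.group,
                "seg_split": "test" if sid in test_ids else "train",
                "mean_t2s": mean_t2s,
                "mean_t2s_truth_mask": masked_mean_t2s(maps[sid], masks[sid]),
                "dice": dice(pred_masks[sid], masks[sid]),
            }
            records.append(rec)
    except Exception as e:  # noqa: BLE001
        raise StageError("mean_t2s", str(e)) from e

    try:
        df = pd.DataFrame(records)
        low = df[df.group == "low_risk"]
        model = TLSGPNormativeModel(
            sigma_eps=config.sigma_eps,
            sigma_delta=config.sigma_delta,
            random_state=int(seeds[3]),
        )
        model.fit(low[["ga_weeks", "mean_t2s"]].to_numpy())
        X = df[["ga_weeks", "mean_t2s"]].to_numpy()
        df["z"] = model.z_score(X)
        df["prob_accel_aging"] = model.prob_accelerated_aging(
            X, n_samples=config.n_mc_samples, random_state=int(seeds[3])
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("health_model", str(e)) from e

    manifest["subjects"] = df.to_dict(orient="records")
    manifest["records_hash"] = hashlib.sha256(
        df.round(10).to_csv(index=False).encode()
    ).hexdigest()[:16]

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "scored_subjects.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        manifest["outputs"] = [str(out / "scored_subjects.csv"), str(out / "manifest.json")]
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
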