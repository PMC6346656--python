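"""End-to-end orchestration: synthesize/load -> preprocess -> markers ->
merge -> model -> classify -> report, with a provenance manifest.

A run is driven by a single JSON-style configuration (see :class:`RunConfig`)
and writes everything into one output directory:

* ``markers.csv`` — one row per subject: 12 EEG markers (+ epoch counts),
  13 ICV-normalized MRI features, covariates and outcomes;
* ``model.json`` — the AICc-selected marker subset with coefficients,
  p-values, R^2 and the top-ranked subsets for audit;
* ``classification.json`` + ``predictions_<set>.csv`` — LOOCV metrics and
  per-fold predictions for MRI-only, EEG-only and combined feature sets;
* ``manifest.json`` — every stage with its parameters and the SHA-256 of
  every file it wrote, so any number in the report is traceable; on a stage
  failure the manifest marks the failure point and partial outputs remain.

Reruns with the same configuration and seed reproduce all numeric outputs
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, classification, preprocessing, synthetic
from .errors import ConfigError
from .markers import EEG_MARKER_NAMES, MarkerConfig, compute_marker_vector
from .mri import MRI_FEATURE_NAMES, normalize_by_icv, read_feature_table
from .recording import read_csv

_RUN_CONFIG_KEYS = {
    "out_dir", "seed", "synthesis", "eeg_dir", "mri_csv", "demographics_csv",
    "max_size", "candidates", "svm", "marker", "preprocessing",
}


@dataclass
class RunConfig:
    """Validated run configuration.

    Either ``synthesis`` (keyword overrides for the synthetic cohort) or the
    three input paths (``eeg_dir`` with ``<subject>_<PHASE>.csv`` files,
    ``mri_csv``, ``demographics_csv`` including mmse/cdr) must be given.
    Unknown keys are rejected before any computation.
    """

    out_dir: str
    seed: int = 0
    synthesis: dict | None = None
    eeg_dir: str | None = None
    mri_csv: str | None = None
    demographics_csv: str | None = None
    max_size: int = 6
    candidates: list[str] | None = None
    svm: dict = field(default_factory=dict)
    marker: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _RUN_CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("configuration requires 'out_dir'")
        cfg = cls(**raw)
        if cfg.synthesis is None and not (
            cfg.eeg_dir and cfg.mri_csv and cfg.demographics_csv
        ):
            raise ConfigError(
                "configuration needs either a 'synthesis' block or all of "
                "eeg_dir, mri_csv and demographics_csv"
            )
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.doc = {
            "config": dataclasses.asdict(config),
            "stages": [],
            "status": "running",
        }

    def stage(self, name: str, params: dict, outputs: list[Path]) -> None:
        self.doc["stages"].append(
            {
                "name": name,
                "params": params,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )
        self.write()

    def fail(self, name: str, error: Exception) -> None:
        self.doc["status"] = f"failed at {name}: {type(error).__name__}: {error}"
        self.write()

    def finish(self) -> None:
        self.doc["status"] = "complete"
        self.write()

    def write(self) -> None:
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(self.doc, fh, indent=1, default=str)


def _svm_grid(svm_cfg: dict) -> list[dict[str, float]]:
    c_lo, c_hi, c_step = svm_cfg.get("c_exponents", [-3, 9, 2])
    g_lo, g_hi, g_step = svm_cfg.get("gamma_exponents", [-11, 3, 2])
    return [
        {"C": float(2.0**c), "gamma": float(2.0**g)}
        for c in range(c_lo, c_hi + 1, c_step)
        for g in range(g_lo, g_hi + 1, g_step)
    ]


def compute_subject_markers(
    rec_by_phase: dict, pp_cfg: preprocessing.PreprocessingConfig,
    mk_cfg: MarkerConfig, subject_id: str,
) -> dict:
    """Preprocess one subject's REC and ENC recordings and extract markers."""
    es = {
        phase: preprocessing.preprocess(rec, pp_cfg)
        for phase, rec in rec_by_phase.items()
    }
    mv = compute_marker_vector(es["REC"], es["ENC"], mk_cfg, subject_id=subject_id)
    row = {"subject_id": subject_id, **mv.to_dict()}
    row["n_epochs_rec"] = mv.n_epochs_rec
    row["n_epochs_enc"] = mv.n_epochs_enc
    return row


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    pp_cfg = preprocessing.PreprocessingConfig(**config.preprocessing)
    pp_cfg.ica_seed = config.seed
    mk_cfg = MarkerConfig(**config.marker)

    stage = "inputs"
    try:
        if config.synthesis is not None:
            syn = dict(config.synthesis)
            syn.setdefault("seed", config.seed)
            cohort = synthetic.CohortConfig(**syn)
            n = cohort.n_subjects
            recordings = {
                i: {
                    phase: synthetic.generate_eeg(cohort, i, phase)
                    for phase in ("REC", "ENC")
                }
                for i in range(n)
            }
            mri_raw = synthetic.generate_mri_table(cohort)
            demographics = synthetic.generate_demographics(cohort)
        else:
            eeg_dir = Path(config.eeg_dir)
            mri_raw = read_feature_table(config.mri_csv)
            demographics = pd.read_csv(config.demographics_csv)
            cohort = None
            recordings = {}
            for i, sid in enumerate(mri_raw["subject_id"]):
                recordings[i] = {
                    phase: read_csv(eeg_dir / f"{sid}_{phase}.csv")
                    for phase in ("REC", "ENC")
                }
            n = len(recordings)
        manifest.stage(stage, {"n_subjects": n, "seed": config.seed}, [])

        stage = "preprocess+markers"
        rows = []
        for i in range(n):
            sid = f"S{i:03d}" if config.synthesis is not None else str(
                mri_raw["subject_id"].iloc[i]
            )
            rows.append(
                compute_subject_markers(recordings[i], pp_cfg, mk_cfg, sid)
            )
        eeg_markers = pd.DataFrame(rows)

        mri_raw.attrs["icv_normalized"] = False
        mri_norm = normalize_by_icv(mri_raw)
        marker_table = (
            mri_norm[["subject_id", *MRI_FEATURE_NAMES]]
            .merge(eeg_markers, on="subject_id")
        )

        stage = "outcomes"
        if config.synthesis is not None:
            outcomes, truth = synthetic.generate_outcomes(
                cohort, marker_table, demographics
            )
            synthetic.write_ground_truth_json(out / "ground_truth.json", cohort, truth)
        else:
            outcomes = demographics

        table = association.make_cohort_table(marker_table, outcomes)
        full = marker_table.merge(outcomes, on="subject_id")
        full.to_csv(out / "markers.csv", index=False)
        manifest.stage(
            stage,
            {"markers": list(marker_table.columns)},
            [out / "markers.csv"]
            + ([out / "ground_truth.json"] if config.synthesis is not None else []),
        )

        stage = "model"
        selection = association.all_subset_select(
            table, candidates=config.candidates, max_size=config.max_size
        )
        best = selection.best
        model_doc = {
            "subset": list(best.subset),
            "r2": best.r2,
            "adj_r2": best.adj_r2,
            "aicc": best.aicc,
            "f": best.fvalue,
            "f_p": best.f_pvalue,
            "n": best.n,
            "coefficients": {
                k: {"beta": float(best.params[k]), "p": float(best.pvalues[k])}
                for k in best.params.index
            },
            "top_subsets": [
                {"subset": list(s), "aicc": a, "r2": r}
                for s, a, r in selection.ranked
            ],
            "n_fits": selection.n_fits,
        }
        with open(out / "model.json", "w") as fh:
            json.dump(model_doc, fh, indent=1)
        manifest.stage(stage, {"max_size": config.max_size}, [out / "model.json"])

        stage = "classify"
        mri_feats = [m for m in best.subset if m in MRI_FEATURE_NAMES]
        eeg_feats = [m for m in best.subset if m in EEG_MARKER_NAMES]
        grid = _svm_grid(config.svm)
        inner = config.svm.get("inner_folds", 5)
        if mri_feats and eeg_feats:
            reports = classification.modality_comparison(
                table, mri_feats, eeg_feats, grid=grid, seed=config.seed,
                inner_folds=inner,
            )
        else:
            feats = list(best.subset) or config.candidates or table.attrs["markers"]
            reports = {
                "selected": classification.loocv_svm(
                    table, list(feats), grid=grid, seed=config.seed,
                    inner_folds=inner, feature_set="selected",
                )
            }
        cls_doc = {}
        outputs = []
        for label, rep in reports.items():
            cm = rep.confusion
            cls_doc[label] = {
                "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
                "metrics": rep.metrics,
            }
            pred_path = out / f"predictions_{label.replace('+', '_')}.csv"
            rep.predictions.to_csv(pred_path, index=False)
            outputs.append(pred_path)
        with open(out / "classification.json", "w") as fh:
            json.dump(cls_doc, fh, indent=1)
        outputs.append(out / "classification.json")
        manifest.stage(stage, {"grid_size": len(grid), "inner_folds": inner}, outputs)

        manifest.finish()
    except Exception as err:  # partial outputs stay; manifest records the point
        manifest.fail(stage, err)
        raise
    return out
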