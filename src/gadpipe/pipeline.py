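"""End-to-end orchestration: cohort -> epochs -> features -> selection ->
classification -> consolidated report.

A single :class:`RunConfig` drives every stage; all randomness flows from
one master seed through named substreams (synthesis, splits, learner
initialisation), so a run directory can be reproduced bit-identically from
its manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .montage import BAND_NAMES
from .preprocess import Recording, concat_epochs, preprocess_recording
from .features import FeatureTable, FuzzyParams, build_feature_table
from .select import anova_select, direction_summary, frontal_edge_ratio
from .classify import ModelSpec, per_band_eval, reports_to_frame
from .synth import CohortSpec, generate_cohort
from . import io as gio


_STAGE_OFFSETS = {"synth": 1, "splits": 2, "learners": 3, "permutation": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Named substream seeds derived from the master seed (stable across runs)."""
    return int(
        np.random.SeedSequence((master_seed, _STAGE_OFFSETS[stage])).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    # input: exactly one of synth_spec / recording_dir
    synth_spec: CohortSpec | None = None
    recording_dir: str | None = None

    target_fs: float = 100.0
    broadband: tuple[float, float] = (4.0, 30.0)
    window_s: float = 4.0
    overlap_frac: float = 0.5

    families: tuple[str, ...] = ("PSD", "FE", "PLI")
    fe_m: int = 2
    fe_k: float = 0.2

    alpha: float = 0.05
    per_subject_selection: bool = False
    fdr: bool = False

    models: tuple[str, ...] = ("svm_rbf", "random_forest", "bp_bagging")
    model_overrides: dict = field(default_factory=dict)
    n_repeats: int = 10
    test_frac: float = 0.2
    subject_split: bool = False

    out_dir: str = "gadpipe_run"
    seed: int = 0
    export_edf: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synth_spec is not None:
            d["synth_spec"] = self.synth_spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synth_spec"):
            d["synth_spec"] = CohortSpec.from_dict(d["synth_spec"])
        for key in ("broadband", "families", "models"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def load_recordings(config: RunConfig) -> list[Recording]:
    """Synthesize a cohort or read recordings from a directory.

    A directory entry point accepts ``*.edf`` files or text recordings
    (``*.tsv`` with a JSON sidecar).
    """
    if (config.synth_spec is None) == (config.recording_dir is None):
        raise ValueError("configure exactly one of synth_spec / recording_dir")
    if config.synth_spec is not None:
        spec = config.synth_spec
        return generate_cohort(spec)
    recs = []
    root = Path(config.recording_dir)
    for p in sorted(root.glob("*.edf")):
        recs.append(gio.read_edf(p, subject_id=p.stem))
    for p in sorted(root.glob("*.tsv")):
        if p.name == "manifest.tsv":
            continue
        recs.append(gio.read_text_recording(p))
    if not recs:
        raise ValueError(f"no recordings found under {root}")
    return recs


def topographic_export(table: FeatureTable, per_subject: bool = True) -> pd.DataFrame:
    """Group-mean PSD/FE value per channel and band, plus relative difference.

    For each univariate feature the group mean is computed by first
    averaging epochs within subject and then across subjects (set
    ``per_subject=False`` for a plain epoch-level mean).  The relative
    difference is ``|mean_GAD - mean_HC| / mean_HC``.
    """
    groups = table.row_meta["group"].to_numpy()
    labels = list(pd.unique(groups))
    rows = []
    for i, col in enumerate(table.columns):
        if col.kind not in ("PSD", "FE"):
            continue
        means = {}
        for lab in labels:
            vals = table.values[groups == lab, i]
            if per_subject:
                subj = table.row_meta["subject_id"].to_numpy()[groups == lab]
                vals = pd.Series(vals).groupby(subj).mean().to_numpy()
            means[lab] = float(np.mean(vals))
        for lab in labels:
            rows.append(
                {
                    "kind": col.kind,
                    "band": col.band,
                    "channel": col.channels[0],
                    "group": lab,
                    "mean": means[lab],
                }
            )
    df = pd.DataFrame(rows)
    if {"GAD", "HC"} <= set(labels):
        wide = df.pivot_table(
            index=["kind", "band", "channel"], columns="group", values="mean"
        ).reset_index()
        wide["rel_diff"] = (wide["GAD"] - wide["HC"]).abs() / wide["HC"]
        df = df.merge(wide[["kind", "band", "channel", "rel_diff"]],
                      on=["kind", "band", "channel"])
    return df


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and write the consolidated report.

    Outputs under ``config.out_dir``: ``features.csv``, ``selection.csv``,
    ``directions.csv``, ``evaluation.csv``, ``topography.csv``,
    ``epoch_index.csv``, ``summary.json`` and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        def fail(exc):
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return fail

    try:
        recordings = load_recordings(config)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        _stage("input")(exc)
    if config.export_edf:
        gio.export_cohort_edf(recordings, out / "edf", seed=config.seed)

    try:
        epoch_sets = [
            preprocess_recording(
                rec,
                target_fs=config.target_fs,
                broadband=config.broadband,
                window_s=config.window_s,
                overlap_frac=config.overlap_frac,
            )
            for rec in recordings
        ]
        epochs = concat_epochs(epoch_sets)
    except Exception as exc:
        _stage("preprocess")(exc)

    try:
        table = build_feature_table(
            epochs,
            families=config.families,
            fe_params=FuzzyParams(m=config.fe_m, k=config.fe_k),
        )
    except Exception as exc:
        _stage("features")(exc)
    table.to_csv(out / "features.csv")
    pd.DataFrame(
        {
            "subject_id": epochs.subject_ids,
            "group": epochs.groups,
            "offset_samples": epochs.offsets,
        }
    ).to_csv(out / "epoch_index.csv", index=False)

    try:
        selected = anova_select(
            table,
            alpha=config.alpha,
            per_subject=config.per_subject_selection,
            fdr=config.fdr,
        )
    except Exception as exc:
        _stage("select")(exc)
    selected.to_csv(out / "selection.csv")
    directions = direction_summary(table, selected)
    directions.to_csv(out / "directions.csv", index=False)
    try:
        fr = frontal_edge_ratio(selected)
    except ValueError:
        fr = None

    topographic_export(table).to_csv(out / "topography.csv", index=False)

    split_seed = stage_seed(config.seed, "splits")
    reports = {}
    try:
        for kind in config.models:
            spec = ModelSpec(kind=kind, **config.model_overrides.get(kind, {}))
            reports[kind] = per_band_eval(
                table,
                selected,
                spec,
                n_repeats=config.n_repeats,
                test_frac=config.test_frac,
                seed=split_seed,
                subject_split=config.subject_split,
            )
    except Exception as exc:
        _stage("classify")(exc)
    eval_df = reports_to_frame(reports)
    eval_df.to_csv(out / "evaluation.csv", index=False)

    n_pli_retained = int(selected.counts.loc[
        selected.counts["kind"] == "PLI", "retained"
    ].sum()) if selected.counts is not None else 0
    lower = (directions["kind"] == "PLI") & (directions["sign"] < 0)
    summary = {
        "n_epochs": table.n_epochs,
        "n_features": table.n_features,
        "n_retained": selected.n_retained,
        "retained_by_family_band": selected.counts.to_dict("records"),
        "frontal_edge_ratio": fr,
        "n_pli_retained": n_pli_retained,
        "pli_lower_in_patients_frac": (
            float(lower.sum() / max(1, (directions["kind"] == "PLI").sum()))
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "gadpipe_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
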