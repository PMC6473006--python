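"""End-to-end orchestration: simulate → preprocess → features →
classify → evaluate, with machine-readable, reproducible reports.

A run is described by a :class:`RunConfig` (loadable from YAML).  The
pipeline either simulates a cohort or loads one from a cohort
directory (as written by :func:`frontoboost.synthetic.write_cohort`),
masks artifacts, extracts the 12 EEG and 8 symptom variables, applies
the consistency and correlation screens, then runs LOOCV boosting and
the class-weight ROC family for each requested variable case.
Identical config + seed ⇒ identical report bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boost, preprocess, roc, spectral, symptoms, synthetic
from .errors import ConfigurationError
from .io import extract_segment, read_recording

logger = logging.getLogger("frontoboost")

CASES = ("eeg_only", "symptoms_only", "combined")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_figures",
           "load_cohort_dir", "extract_features"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    # input: either a cohort directory or a simulation spec
    cohort_dir: str | None = None
    simulate: bool = True
    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    # segment / preprocessing
    segment_label: str = "eyes_closed"
    segment_repeat: str = "first"
    rail_uV: float = 400.0
    excursion_uV: float = 200.0
    apply_masks: bool = True
    # features
    psd_window: str = "hann"
    smooth: bool = True
    # screens
    consistency_screen: bool = True
    # classification
    boost: boost.BoostConfig = field(default_factory=boost.BoostConfig)
    cases: tuple[str, ...] = CASES
    weight_grid: tuple[int, ...] = tuple(range(1, 11))
    subset_search: bool = False
    subset_cardinality: tuple[int, ...] | None = None
    seed: int = 0
    # cosmetic (excluded from the config hash)
    log_level: str = "INFO"
    figure_dpi: int = 110

    _COSMETIC = ("log_level", "figure_dpi")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        for k in self._COSMETIC:
            payload.pop(k, None)
        blob = json.dumps(payload, sort_keys=True, default=repr)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.simulate:
            self.cohort.validate()
        elif not self.cohort_dir:
            raise ConfigurationError("need cohort_dir when simulate=False")
        unknown = set(self.cases) - set(CASES)
        if unknown:
            raise ConfigurationError(f"unknown cases {sorted(unknown)}")
        if self.segment_repeat not in ("first", "second", "concatenate"):
            raise ConfigurationError(
                f"bad segment_repeat {self.segment_repeat!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown config key {key!r}")
            if key == "cohort":
                cfg.cohort = synthetic.CohortSpec(**val)
            elif key == "boost":
                cfg.boost = boost.BoostConfig(**val)
            else:
                setattr(cfg, key, val)
        cfg.cases = tuple(cfg.cases)
        cfg.weight_grid = tuple(cfg.weight_grid)
        return cfg


@dataclass
class RunReport:
    config_hash: str
    seed: int
    n_subjects: int
    removed_subjects: list[str]
    screen: pd.DataFrame
    cases: dict[str, dict]
    families: dict[str, "roc.ROCFamily"]
    cv: dict[str, "boost.CVResult"]
    subset_ranking: pd.DataFrame | None = None

    def to_json(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "removed_subjects": list(self.removed_subjects),
            "screen": {
                var: {"r": _js(row["r"]), "p": _js(row["p"]),
                      "constant": bool(row["constant"])}
                for var, row in self.screen.iterrows()
            },
            "cases": self.cases,
        }


def _js(x):
    x = float(x)
    return None if np.isnan(x) else x


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def load_cohort_dir(path) -> list[synthetic.SyntheticSubject]:
    """Load a cohort directory written by :func:`synthetic.write_cohort`."""
    path = Path(path)
    table = path / "symptoms.csv"
    if not table.exists():
        raise FileNotFoundError(
            f"symptoms stage input missing: {table} not found"
        )
    df = pd.read_csv(table)
    subjects = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        rec_path = path / f"{sid}.csv"
        if not rec_path.exists():
            rec_path = path / f"{sid}.edf"
        rec = read_recording(rec_path)
        answers = {i: bool(row[i]) for i in symptoms.SYMPTOM_ITEMS}
        sevs = {i: int(row[f"{i}_severity"]) for i in symptoms.SYMPTOM_ITEMS}
        annots = []
        ann_path = path / f"{sid}.annotations.json"
        if ann_path.exists():
            with open(ann_path) as fh:
                for a in json.load(fh)["artifacts"]:
                    annots.append(synthetic.ArtifactAnnotation(**a))
        subjects.append(
            synthetic.SyntheticSubject(
                subject_id=sid, label=row["label"], recording=rec,
                symptoms=symptoms.SymptomReport(answers, sevs),
                artifacts=annots,
            )
        )
    return subjects


def extract_features(subject, config: RunConfig) -> pd.Series:
    """Segment → artifact masks → 12 log band-power features."""
    rec = subject.recording
    try:
        seg = extract_segment(rec, config.segment_label, config.segment_repeat)
    except Exception:
        seg = None
    target = seg if seg is not None else rec
    mask = None
    if config.apply_masks:
        masks = preprocess.run_all_detectors(
            target, rail_uV=config.rail_uV, excursion_uV=config.excursion_uV
        )
        mask = preprocess.combine_masks(*masks.values())
    filtered = preprocess.bandpass(
        rec if seg is None else
        type(rec)(seg.data, rec.fs, rec.channels)
    )
    return spectral.eeg_features(
        filtered, mask=mask, window=config.psd_window, smooth=config.smooth
    )


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Execute all stages; optionally write stage outputs under ``outdir``."""
    config.validate()
    t0 = time.time()
    if config.simulate:
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        subjects = synthetic.generate_cohort(spec)
        stage = "simulate"
    else:
        subjects = load_cohort_dir(config.cohort_dir)
        stage = "load"
    logger.info("%s: %d subjects (%.1fs)", stage, len(subjects),
                time.time() - t0)

    t0 = time.time()
    eeg_rows = {}
    for s in subjects:
        try:
            eeg_rows[s.subject_id] = extract_features(s, config)
        except Exception as exc:
            raise RuntimeError(
                f"features stage failed for subject {s.subject_id}: {exc}"
            ) from exc
    eeg = pd.DataFrame(eeg_rows).T
    logger.info("features: %s (%.1fs)", eeg.shape, time.time() - t0)

    sym = symptoms.symptom_table(subjects)
    removed_ids: list[str] = []
    if config.consistency_screen:
        sym, removed = symptoms.consistency_screen(sym)
        removed_ids = list(removed.index)
        eeg = eeg.loc[sym.index]
    labels = sym["label"].to_numpy()
    sym_vars = sym.drop(columns="label")
    screen = symptoms.variable_class_correlation(
        pd.concat([eeg, sym_vars], axis=1), labels
    )

    cases_out: dict[str, dict] = {}
    families: dict[str, roc.ROCFamily] = {}
    cvs: dict[str, boost.CVResult] = {}
    for case in config.cases:
        t0 = time.time()
        fm = boost.assemble(eeg, sym_vars, labels, case)
        cv = boost.loocv(fm, config.boost)
        fam = roc.roc_family(fm, config.boost, config.weight_grid)
        ok = np.isfinite(cv.scores)
        dist = roc.score_distributions(cv.scores[ok], cv.y[ok])
        cases_out[case] = {
            "n_variables": fm.X.shape[1],
            "loocv_accuracy": cv.accuracy,
            "resubstitution_accuracy": cv.resubstitution_accuracy,
            "auc_mean": fam.auc_mean,
            "auc_min": fam.auc_min,
            "auc_max": fam.auc_max,
            "n_roc_members": fam.n_members,
            "score_separation": dist.separation,
        }
        families[case] = fam
        cvs[case] = cv
        logger.info("case %s: acc=%.3f auc=%.3f (%.1fs)", case, cv.accuracy,
                    fam.auc_mean, time.time() - t0)

    ranking = None
    if config.subset_search:
        ranking = boost.subset_search(
            eeg, sym_vars, labels, config.boost,
            cardinality=config.subset_cardinality,
        )

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        n_subjects=len(sym),
        removed_subjects=removed_ids,
        screen=screen,
        cases=cases_out,
        families=families,
        cv=cvs,
        subset_ranking=ranking,
    )
    if outdir is not None:
        _write_outputs(report, config, Path(outdir))
    return report


def _write_outputs(report: RunReport, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.screen.to_csv(outdir / "screen.csv")
    for case, cv in report.cv.items():
        cv.to_frame().to_csv(outdir / f"cv_{case}.csv", index=False)
        fam = report.families[case]
        pd.DataFrame(
            {"fpr": fam.fpr_grid, "tpr_mean": fam.tpr_mean,
             "tpr_min": fam.tpr_min, "tpr_max": fam.tpr_max}
        ).to_csv(outdir / f"roc_{case}.csv", index=False)
    if report.subset_ranking is not None:
        report.subset_ranking.to_csv(outdir / "subset_ranking.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(report: RunReport, outdir, fmt: str = "svg") -> dict:
    """Render the ROC-family / ordered-score / distribution panel grid.

    One column per case, three rows (ROC family with mean and min–max
    band; ordered held-out scores at equal class weights; per-class
    score distributions).  Returns ``{"path": ..., "n_panels": ...}``.
    Rendering is deterministic for a given report.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matplotlib.rcParams["svg.hashsalt"] = "frontoboost"  # reproducible ids

    cases = [c for c in CASES if c in report.families]
    if not cases:
        raise ValueError("report contains no completed cases to plot")
    missing = [c for c in report.cases if c not in report.families]
    if missing:
        raise ValueError(f"report incomplete; missing panels for {missing}")
    fig, axes = plt.subplots(
        3, len(cases), figsize=(4 * len(cases), 10), squeeze=False
    )
    for j, case in enumerate(cases):
        fam = report.families[case]
        cv = report.cv[case]
        ax = axes[0][j]
        ax.fill_between(fam.fpr_grid, fam.tpr_min, fam.tpr_max, alpha=0.25,
                        color="C0", label="min–max")
        ax.plot(fam.fpr_grid, fam.tpr_mean, "C0",
                label=f"mean (AUC={fam.auc_mean:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set(title=case, xlabel="false-positive rate",
               ylabel="true-positive rate")
        ax.legend(loc="lower right", fontsize=8)

        ax = axes[1][j]
        ordered = roc.ordered_scores(cv.scores, cv.y)
        colors = np.where(ordered["label"] > 0, "red", "blue")
        ax.bar(np.arange(len(ordered)), ordered["score"], color=colors)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set(xlabel="subject (ordered)", ylabel="score")

        ax = axes[2][j]
        sc, y = cv.scores, cv.y
        ok = np.isfinite(sc)
        ax.hist(sc[ok & (y > 0)], bins=15, alpha=0.6, color="red",
                label="mTBI", density=True)
        ax.hist(sc[ok & (y < 0)], bins=15, alpha=0.6, color="blue",
                label="control", density=True)
        ax.set(xlabel="score", ylabel="density")
        ax.legend(fontsize=8)
    fig.tight_layout()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"roc_panel.{fmt}"
    meta = {"Date": None} if fmt == "svg" else None
    fig.savefig(path, dpi=110, metadata=meta)
    plt.close(fig)
    return {"path": str(path), "n_panels": 3 * len(cases)}
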