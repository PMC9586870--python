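"""Tumor/healthy detection from cfDNA methylation features.

An ensemble of gradient-boosted tree classifiers (default 100 members,
500 trees, learning rate 0.02) is trained on synthetic spike-in mixtures
over a panel of detection windows (DMRs against both healthy tissue and
training NCC cfDNA). Each member sees mixtures built from 80% of the tumor
sources and 80% of the background sources; a sample's score is the median
over members, and the decision cutoff is the grid value optimizing
balanced accuracy on out-of-bag mixtures.

Per-window features are beta-values with missing encoded as 0: bounded and
depth-invariant, so mixtures at different fragment totals live on a common
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .containers import derive_rng

_S_DETECT = 202

DEFAULT_XGB_PARAMS = {"n_estimators": 500, "learning_rate": 0.02}


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Average of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def _make_classifier(**params) -> XGBClassifier:
    clf = XGBClassifier(**params)
    # scikit-learn >= 1.9 dropped the class-level _estimator_type attribute
    # that xgboost's model (de)serialization still consults
    clf._estimator_type = "classifier"
    return clf


@dataclass
class CutoffResult:
    cutoff: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class EnsembleModel:
    """A fitted ensemble with per-member training provenance.

    ``member_sources`` records, per member, the tumor and background source
    subsets whose mixtures it saw — the basis for source-leakage-free
    prediction and out-of-bag cutoff derivation.
    """

    feature_windows: list
    members: list
    member_sources: list
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_scores(self, features: pd.DataFrame) -> np.ndarray:
        """(members x samples) prediction scores."""
        x = features[self.feature_windows].to_numpy(dtype=float)
        return np.vstack([m.predict_proba(x)[:, 1] for m in self.members])

    def eligible_members(self, exclude_sources) -> np.ndarray:
        """Boolean mask of members whose training sources avoid ``exclude_sources``."""
        excl = set(exclude_sources or [])
        return np.array([
            not (excl & (set(src["tumor"]) | set(src["background"])))
            for src in self.member_sources])


# ---------------------------------------------------------------------------
# window selection and features
# ---------------------------------------------------------------------------

def select_detection_windows(
    dmrs_vs_healthy_tissue: pd.DataFrame,
    dmrs_vs_training_ncc: pd.DataFrame,
) -> pd.DataFrame:
    """Direction-consistent intersection of two filtered DMR tables.

    Both inputs should already be filtered (FDR 0.001, |delta beta| >= 0.5
    for tissue-level contrasts). Raises when the intersection is empty —
    there is nothing to train on.
    """
    merged = dmrs_vs_healthy_tissue.merge(
        dmrs_vs_training_ncc, on="window", suffixes=("_tissue", "_ncc"))
    merged = merged[merged["direction_tissue"] == merged["direction_ncc"]]
    if merged.empty:
        raise ValueError("no direction-consistent windows shared by the two contrasts")
    out = merged[["window"]].copy()
    out["direction"] = merged["direction_tissue"].to_numpy()
    return out.sort_values("window").reset_index(drop=True)


def build_feature_matrix(
    beta: pd.DataFrame,
    feature_windows,
) -> pd.DataFrame:
    """One row per sample, one column per feature window; missing beta -> 0.

    Column order follows ``feature_windows`` and is identical across train
    and predict calls by construction.
    """
    feature_windows = list(feature_windows)
    missing = set(feature_windows) - set(beta.index)
    if missing:
        raise KeyError(f"feature windows absent from beta matrix: {sorted(missing)[:5]}")
    return beta.loc[feature_windows].T.fillna(0.0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _default_sampler(tumor_pool, background_pool, subsample, rng):
    n_t = max(1, int(round(subsample * len(tumor_pool))))
    n_b = max(1, int(round(subsample * len(background_pool))))
    return {
        "tumor": sorted(rng.choice(tumor_pool, size=n_t, replace=False).tolist()),
        "background": sorted(rng.choice(background_pool, size=n_b, replace=False).tolist()),
    }


def manifest_sources(manifest: pd.DataFrame) -> tuple[list, list]:
    """Tumor and background source pools recorded in a mixture manifest."""
    tumor = sorted(manifest["tumor_source"].dropna().unique().tolist())
    bg = set(manifest["background_source"].dropna())
    if "background_source_2" in manifest:
        bg |= set(manifest["background_source_2"].dropna())
    return tumor, sorted(bg)


def _eligible_rows(manifest: pd.DataFrame, sources: dict) -> np.ndarray:
    t_set, b_set = set(sources["tumor"]), set(sources["background"])
    ok_t = manifest["tumor_source"].isna() | manifest["tumor_source"].isin(t_set)
    ok_b = manifest["background_source"].isin(b_set)
    if "background_source_2" in manifest:
        ok_b &= (manifest["background_source_2"].isna()
                 | manifest["background_source_2"].isin(b_set))
    return (ok_t & ok_b).to_numpy()


def train_ensemble(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    label_col: str = "label",
    n_members: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    xgb_params: dict | None = None,
    source_sampler=None,
    max_retries: int = 10,
) -> EnsembleModel:
    """Train the source-subsampled gradient-boosted ensemble.

    ``features`` is indexed by mixture id (columns = feature windows);
    ``manifest`` carries source columns and the binary label. Each member
    trains only on mixtures whose every source lies in that member's
    subsets (a strict rule, applied to both background sources of negative
    mixtures). Members that draw a single-class training set are resampled
    up to ``max_retries`` times before raising.
    """
    params = dict(DEFAULT_XGB_PARAMS)
    if xgb_params:
        params.update(xgb_params)
    manifest = manifest.set_index("mixture_id").loc[features.index].reset_index()
    tumor_pool, bg_pool = manifest_sources(manifest)
    if not bg_pool:
        raise ValueError("manifest names no background sources")
    y_all = manifest[label_col].to_numpy()
    x_all = features.to_numpy(dtype=float)
    rng = derive_rng(seed, _S_DETECT)

    members, member_sources = [], []
    for i in range(n_members):
        for attempt in range(max_retries + 1):
            if source_sampler is not None:
                sources = source_sampler(rng)
            else:
                sources = _default_sampler(tumor_pool, bg_pool, subsample, rng)
            rows = _eligible_rows(manifest, sources)
            if rows.any() and len(np.unique(y_all[rows])) == 2:
                break
        else:
            raise RuntimeError(
                f"member {i}: could not draw a two-class training subset "
                f"in {max_retries + 1} attempts")
        clf = _make_classifier(**params,
                               random_state=int(rng.integers(0, 2 ** 31 - 1)),
                               n_jobs=1, eval_metric="logloss")
        clf.fit(x_all[rows], y_all[rows])
        members.append(clf)
        member_sources.append(sources)
    return EnsembleModel(
        feature_windows=list(features.columns),
        members=members,
        member_sources=member_sources,
        metadata={"n_members": n_members, "subsample": subsample,
                  "seed": seed, "xgb_params": params, "label_col": label_col},
    )


# ---------------------------------------------------------------------------
# prediction and cutoff
# ---------------------------------------------------------------------------

def predict_median_score(
    model: EnsembleModel,
    features: pd.DataFrame,
    exclude_sources=None,
) -> pd.DataFrame:
    """Median ensemble score per sample over leakage-free members.

    Members whose training sources intersect ``exclude_sources`` (for
    example the CDX model matched to a patient's cfDNA) are dropped before
    taking the median; raises when no member remains.
    """
    mask = model.eligible_members(exclude_sources)
    if not mask.any():
        raise ValueError("no ensemble member avoids the excluded sources")
    scores = model.member_scores(features)[mask]
    out = pd.DataFrame({
        "median_score": np.median(scores, axis=0),
        "n_members_used": int(mask.sum()),
    }, index=features.index)
    if model.cutoff is not None:
        out["hard_call"] = np.where(out["median_score"] >= model.cutoff,
                                    "SCLC", "NCC")
    return out


def oob_scores(
    model: EnsembleModel,
    features: pd.DataFrame,
    manifest: pd.DataFrame,
) -> pd.Series:
    """Out-of-bag median score per training mixture.

    For each mixture, the median over members that could not have seen it
    during training (some source outside the member's subsets). Mixtures
    seen by every member come back NaN.
    """
    manifest = manifest.set_index("mixture_id").loc[features.index].reset_index()
    scores = model.member_scores(features)
    eligible = np.vstack([_eligible_rows(manifest, src)
                          for src in model.member_sources])
    oob = np.where(~eligible, scores, np.nan)
    with np.errstate(all="ignore"):
        med = np.nanmedian(oob, axis=0)
    return pd.Series(med, index=features.index, name="oob_median_score")


def derive_cutoff(
    y_true: np.ndarray,
    scores: np.ndarray,
    grid_step: float = 0.01,
) -> CutoffResult:
    """Balanced-accuracy-optimal score cutoff over a regular grid.

    Evaluates every grid value in [0, 1] and returns the smallest one
    attaining the maximum balanced accuracy (deterministic tie-break that
    favors sensitivity), with sensitivity and specificity at that cutoff.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    ok = ~np.isnan(s)
    y, s = y[ok], s[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("cutoff derivation needs both classes present")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    calls = s[None, :] >= grid[:, None]
    pos, neg = y == 1, y == 0
    sens = calls[:, pos].mean(axis=1)
    spec = (~calls[:, neg]).mean(axis=1)
    ba = (sens + spec) / 2.0
    # smallest grid value attaining the optimum (ties resolved explicitly,
    # tolerating float noise between equal rational balanced accuracies)
    best = int(np.flatnonzero(ba >= ba.max() - 1e-12)[0])
    return CutoffResult(cutoff=float(grid[best]),
                        balanced_accuracy=float(ba[best]),
                        sensitivity=float(sens[best]),
                        specificity=float(spec[best]))


def feature_importance(model: EnsembleModel) -> pd.Series:
    """Per-window importance averaged over the ensemble members."""
    imps = np.vstack([m.feature_importances_ for m in model.members])
    return pd.Series(imps.mean(axis=0), index=model.feature_windows,
                     name="importance")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_ensemble(model: EnsembleModel, path) -> None:
    """Serialize a model bundle as a directory (JSON metadata + members)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "feature_windows": [int(w) if isinstance(w, (int, np.integer)) else w
                            for w in model.feature_windows],
        "member_sources": model.member_sources,
        "cutoff": model.cutoff,
        "metadata": model.metadata,
        "n_members": model.n_members,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
    for i, m in enumerate(model.members):
        m.save_model(path / f"member_{i:03d}.json")


def load_ensemble(path) -> EnsembleModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    members = []
    for i in range(meta["n_members"]):
        clf = _make_classifier()
        clf.load_model(path / f"member_{i:03d}.json")
        members.append(clf)
    return EnsembleModel(
        feature_windows=meta["feature_windows"],
        members=members,
        member_sources=meta["member_sources"],
        cutoff=meta["cutoff"],
        metadata=meta["metadata"],
    )
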