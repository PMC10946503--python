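"""Model validation in space and time.

Spatial transferability is assessed by eightfold spatial-block cross
validation: the domain is tiled into square blocks whose edge reflects the
empirical autocorrelation range of the predictors (so held-out blocks are
quasi-independent "novel areas"), blocks are assigned to eight folds, and
eight refits each predict the fold they never saw.  Temporal
transferability holds out the final five survey years (post-2015), lowering
the split year one year at a time when fewer than ten validation presences
are available.  Performance is summarised by ROC AUC, precision–recall AUC
and the Miller calibration slope; a model passes when both spatial and
temporal ROC AUCs reach 0.65.  The presence threshold is the
sensitivity+specificity maximiser over the pooled spatial-CV predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.metrics import precision_recall_curve, roc_auc_score

logger = logging.getLogger(__name__)

AUC_GATE = 0.65
DEFAULT_SPLIT_YEAR = 2015
MIN_VAL_PRESENCES = 10
PROB_CLIP = 1e-6


class UntestableTemporalSplit(ValueError):
    """No split year yields enough validation presences."""


@dataclass
class BlockDesign:
    """Spatial-block CV design: a fold id (1..n_folds) for every grid cell."""

    fold_of_cell: np.ndarray  # (ny, nx) int
    block_edge_cells: int
    autocorr_range_km: float
    n_folds: int
    seed: int

    def fold_for(self, y, x) -> np.ndarray:
        return self.fold_of_cell[np.asarray(y), np.asarray(x)]


def _autocorr_range_cells(field: np.ndarray, cutoff: float = 1.0 / np.e) -> int:
    """Distance (cells) at which the lag correlogram first drops below cutoff."""
    ny, nx = field.shape
    max_lag = max(ny, nx) - 1
    for d in range(1, max_lag + 1):
        cors = []
        if nx > d:
            a, b = field[:, :-d].ravel(), field[:, d:].ravel()
            if a.std() > 0 and b.std() > 0:
                cors.append(np.corrcoef(a, b)[0, 1])
        if ny > d:
            a, b = field[:-d, :].ravel(), field[d:, :].ravel()
            if a.std() > 0 and b.std() > 0:
                cors.append(np.corrcoef(a, b)[0, 1])
        if not cors or np.mean(cors) < cutoff:
            return d
    return max_lag


def build_blocks(fields: xr.Dataset, n_folds: int = 8, seed: int = 0,
                 reference_year: int | None = None) -> BlockDesign:
    """Blocks sized from the predictors' empirical autocorrelation range.

    For each dynamic predictor in a reference year (the year nearest 2000 by
    default) the correlogram range is the first lag where correlation drops
    below 1/e; the block edge is the median range across predictors, rounded
    up to whole cells.  Blocks are then dealt to ``n_folds`` folds by a
    seeded permutation, round-robin so fold sizes stay balanced.
    """
    years = [int(y) for y in fields.year.values]
    ref = reference_year if reference_year is not None else min(years, key=lambda y: abs(y - 2000))
    ny, nx = fields.sizes["y"], fields.sizes["x"]

    ranges = []
    for v in fields.data_vars:
        da = fields[v]
        if "year" not in da.dims:
            continue
        ranges.append(_autocorr_range_cells(da.sel(year=ref).values))
    if not ranges:
        raise ValueError("no dynamic predictors to assess autocorrelation")
    edge = int(np.ceil(np.median(ranges)))
    if edge >= min(ny, nx):
        raise ValueError(
            f"autocorrelation range ({edge} cells) spans the domain: single-block failure")

    def tile(e: int) -> np.ndarray:
        return (np.arange(ny)[:, None] // e) * ((nx + e - 1) // e) + (np.arange(nx)[None, :] // e)

    block_id = tile(edge)
    # gradient-dominated fields can push the range so wide that fewer blocks
    # than folds remain; shrink to the largest edge giving n_folds blocks
    while len(np.unique(block_id)) < n_folds and edge > 1:
        edge -= 1
        block_id = tile(edge)
    blocks = np.unique(block_id)
    if len(blocks) < n_folds:
        raise ValueError(f"only {len(blocks)} blocks for {n_folds} folds")
    if edge < int(np.ceil(np.median(ranges))):
        logger.warning("block edge reduced below the autocorrelation range (%d < %.0f cells) "
                       "to keep %d folds non-empty", edge, np.ceil(np.median(ranges)), n_folds)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 877]))
    order = rng.permutation(blocks)
    fold_of_block = {int(b): (i % n_folds) + 1 for i, b in enumerate(order)}
    fold_of_cell = np.vectorize(fold_of_block.get)(block_id)
    cell_km = float(fields.attrs.get("cell_km", 10.0))
    return BlockDesign(fold_of_cell=fold_of_cell, block_edge_cells=edge,
                       autocorr_range_km=edge * cell_km, n_folds=n_folds, seed=seed)


def spatial_cv(model, design: BlockDesign, random_state: int = 0) -> pd.DataFrame:
    """Pooled out-of-block predictions for a habitat model.

    Eight refits of the model's engine, each excluding one fold and
    predicting it, so every observation is predicted exactly once by a model
    that never saw its block.  Folds whose training split is single-class
    are skipped with a logged coverage gap.
    """
    if model.meta is None or not {"y", "x"}.issubset(model.meta.columns):
        raise ValueError("model.meta with cell coordinates required for spatial CV")
    folds = design.fold_for(model.meta["y"].to_numpy(), model.meta["x"].to_numpy())
    X = model.exog.to_numpy(dtype=float)
    y = model.presence
    parts = []
    for k in range(1, design.n_folds + 1):
        test = folds == k
        if not test.any():
            continue
        train = ~test
        if len(np.unique(y[train])) < 2:
            logger.warning("fold %d skipped: single-class training split (coverage gap)", k)
            continue
        engine = model.engine.clone(random_state + k)
        engine.fit(X[train], y[train])
        pred = engine.predict_draws(X[test]).mean(axis=0)
        parts.append(pd.DataFrame({
            "obs": y[test], "pred": pred, "fold": k,
            "row": np.flatnonzero(test)}))
    if not parts:
        raise ValueError("no usable folds in spatial CV")
    return pd.concat(parts, ignore_index=True)


def temporal_holdout(model, split_year: int = DEFAULT_SPLIT_YEAR,
                     min_val_presences: int = MIN_VAL_PRESENCES,
                     random_state: int = 0) -> tuple[pd.DataFrame, int]:
    """Train before a split year, predict the years from the split onward.

    If the validation period (year >= split) holds fewer than
    ``min_val_presences`` presences, the split is lowered one year at a time;
    when no split year works the species-guild is untestable.
    Returns (pooled predictions, split year used).
    """
    if model.meta is None or "year" not in model.meta.columns:
        raise ValueError("model.meta with a year column required for temporal holdout")
    years = model.meta["year"].to_numpy()
    y = model.presence
    lo = int(years.min())
    split = int(split_year)
    while split > lo:
        val = years >= split
        train = ~val
        if (y[val].sum() >= min_val_presences and train.any()
                and len(np.unique(y[train])) == 2):
            break
        split -= 1
    else:
        raise UntestableTemporalSplit(
            f"no split year achieves {min_val_presences} validation presences")
    if split != split_year:
        logger.info("temporal split lowered from %d to %d", split_year, split)
    val = years >= split
    engine = model.engine.clone(random_state + 97)
    engine.fit(model.exog.to_numpy(dtype=float)[~val], y[~val])
    pred = engine.predict_draws(model.exog.to_numpy(dtype=float)[val]).mean(axis=0)
    return pd.DataFrame({"obs": y[val], "pred": pred}), split


# -- metrics ----------------------------------------------------------------

def roc_auc(obs, pred) -> float:
    """ROC AUC: the Mann–Whitney probability that a random presence scores
    above a random absence (ties count one half)."""
    obs = np.asarray(obs)
    if len(np.unique(obs)) < 2:
        raise ValueError("ROC AUC undefined with a single class")
    return float(roc_auc_score(obs, pred))


def pr_auc(obs, pred) -> float:
    """Precision–recall AUC by trapezoidal integration over recall."""
    obs = np.asarray(obs)
    if len(np.unique(obs)) < 2:
        raise ValueError("PR AUC undefined with a single class")
    precision, recall, _ = precision_recall_curve(obs, pred)
    # several thresholds can share a recall; keep the best achievable
    # precision at each recall before integrating
    df = pd.DataFrame({"r": recall, "p": precision}).groupby("r")["p"].max()
    return float(np.trapezoid(df.to_numpy(), df.index.to_numpy()))


def miller_slope(obs, pred) -> float:
    """Calibration slope: logistic regression of outcome on logit(prediction).

    1 is perfect calibration; below 1 indicates overconfident predictions.
    Probabilities are clipped to [1e-6, 1-1e-6] before the logit.
    Non-convergence (e.g. perfect separation) yields NaN with a warning.
    """
    import statsmodels.api as sm

    p = np.clip(np.asarray(pred, dtype=float), PROB_CLIP, 1 - PROB_CLIP)
    lp = np.log(p / (1 - p))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(np.asarray(obs), sm.add_constant(lp)).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise ValueError("not converged")
        return float(fit.params[1])
    except Exception as e:  # noqa: BLE001 - flagged, not fatal
        logger.warning("Miller slope did not converge: %s", e)
        return float("nan")


def choose_threshold(obs, pred) -> float:
    """Presence threshold maximising sensitivity + specificity on pooled
    spatial-CV predictions (presence when prediction >= threshold).

    Candidates are the observed predicted values plus 0 and 1; ties resolve
    to the smallest maximiser.
    """
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    if len(np.unique(obs)) < 2:
        raise ValueError("threshold undefined with a single class")
    cands = np.unique(np.concatenate([pred, [0.0, 1.0]]))
    pres, absn = pred[obs == 1], pred[obs == 0]
    best_t, best_j = None, -np.inf
    for t in cands:  # ascending, so the first maximiser is the smallest
        j = (pres >= t).mean() + (absn < t).mean()
        if j > best_j:
            best_t, best_j = t, j
    return float(best_t)


@dataclass
class ValidationReport:
    """Spatial and temporal performance of one species-guild model."""

    spatial_roc_auc: float
    spatial_pr_auc: float
    spatial_miller_slope: float
    temporal_roc_auc: float
    temporal_pr_auc: float
    temporal_miller_slope: float
    split_year: int | None
    temporal_untestable: bool = False

    @property
    def passed(self) -> bool:
        """True iff both ROC AUCs reach the 0.65 gate."""
        return (not self.temporal_untestable
                and self.spatial_roc_auc >= AUC_GATE
                and self.temporal_roc_auc >= AUC_GATE)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["passed"] = self.passed
        return d


def validate_model(model, design: BlockDesign | None = None,
                   fields: xr.Dataset | None = None,
                   split_year: int = DEFAULT_SPLIT_YEAR, n_folds: int = 8,
                   seed: int = 0, min_val_presences: int = MIN_VAL_PRESENCES
                   ) -> tuple[ValidationReport, float]:
    """Full validation of one habitat model; returns (report, threshold)."""
    if design is None:
        if fields is None:
            raise ValueError("either a BlockDesign or predictor fields are required")
        design = build_blocks(fields, n_folds=n_folds, seed=seed)
    pooled = spatial_cv(model, design, random_state=seed)
    thr = choose_threshold(pooled["obs"], pooled["pred"])
    s_roc = roc_auc(pooled["obs"], pooled["pred"])
    s_pr = pr_auc(pooled["obs"], pooled["pred"])
    s_ms = miller_slope(pooled["obs"], pooled["pred"])
    try:
        tpool, used_split = temporal_holdout(model, split_year=split_year,
                                             min_val_presences=min_val_presences,
                                             random_state=seed)
        t_roc = roc_auc(tpool["obs"], tpool["pred"])
        t_pr = pr_auc(tpool["obs"], tpool["pred"])
        t_ms = miller_slope(tpool["obs"], tpool["pred"])
        untestable, split_used = False, used_split
    except UntestableTemporalSplit:
        t_roc = t_pr = t_ms = float("nan")
        untestable, split_used = True, None
    report = ValidationReport(s_roc, s_pr, s_ms, t_roc, t_pr, t_ms,
                              split_used, temporal_untestable=untestable)
    return report, thr
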