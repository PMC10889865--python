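"""Nested permuted discriminant function analysis (pDFA).

Tests whether behavioural context predicts the acoustic features of calls
while controlling for repeated measures of individuals and a severely
unbalanced design. Each individual occurs in exactly one context (nested
design), so significance is assessed by permuting context labels across
whole individuals — the unit of exchangeability — never across single calls.

For every (real or permuted) labelling the statistic is built from balanced
selections: the same number of calls per individual enters the discriminant
derivation set, the remaining calls form the validation set, and a linear
discriminant classifies both. Chance levels are the means of the permuted
null distributions, so they automatically absorb the class imbalance.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .schema import ConfigError, DataError, PARAMETER_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PDFASettings:
    """Knobs of the nested pDFA.

    ``n_sel_calls=None`` uses the minimum call count across included
    individuals (no exclusions). The observed statistic is averaged over
    ``k_selections_observed`` random balanced selections; each permutation
    uses ``k_selections_perm`` selections.
    """

    n_sel_calls: Optional[int] = None
    k_selections_observed: int = 100
    k_selections_perm: int = 100
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("need at least one permutation")
        if self.n_sel_calls is not None and self.n_sel_calls < 1:
            raise ConfigError("n_sel_calls must be >= 1")
        if min(self.k_selections_observed, self.k_selections_perm) < 1:
            raise ConfigError("selection counts must be >= 1")


@dataclass
class PDFAResult:
    pct_classified: float
    pct_cross_classified: Optional[float]
    chance_classified: float
    chance_cross_classified: Optional[float]
    relative_cross_classification: Optional[float]
    p_classified: float
    p_cross_classified: Optional[float]
    n_individuals: int
    n_calls: int
    excluded_individuals: List[str]
    settings: Dict = field(default_factory=dict)

    def as_dict(self) -> Dict:
        return asdict(self)


def _lda_train(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    """Closed-form two-class LDA with priors from the class frequencies.

    Returns (weight vector, bias); predict class 1 where x·w + b > 0.
    Equivalent to the classic pooled-covariance discriminant.
    """
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise DataError("derivation set must contain both contexts")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    d0 = X[y == 0] - mu0
    d1 = X[y == 1] - mu1
    cov = (d0.T @ d0 + d1.T @ d1) / max(y.size - 2, 1)
    try:
        w = np.linalg.solve(cov, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise DataError(
            "singular within-class covariance; standardise or drop collinear "
            "features, or select more calls per individual"
        ) from err
    bias = -0.5 * (mu0 + mu1) @ w + np.log(n1 / n0)
    return w, bias


def classify_lda(
    X_der: np.ndarray, y_der: np.ndarray,
    X_val: Optional[np.ndarray], y_val: Optional[np.ndarray],
) -> Tuple[float, Optional[float]]:
    """Fit the discriminant on the derivation set; report % correctly
    classified (derivation) and % correctly cross-classified (validation,
    None when the validation set is empty)."""
    w, b = _lda_train(X_der, y_der)
    pct = 100.0 * np.mean((X_der @ w + b > 0) == (y_der == 1))
    if X_val is None or len(X_val) == 0:
        return float(pct), None
    pct_cross = 100.0 * np.mean((X_val @ w + b > 0) == (y_val == 1))
    return float(pct), float(pct_cross)


def balanced_selection(
    groups: Sequence[np.ndarray], n_sel: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Split call indices into a balanced derivation set (exactly ``n_sel``
    calls per individual, without replacement) and the validation remainder.

    ``groups`` is a list of index arrays, one per individual.
    """
    der, val = [], []
    for idx in groups:
        if idx.size < n_sel:
            raise DataError(
                f"individual with {idx.size} calls reached selection with "
                f"n_sel={n_sel}; exclude upstream"
            )
        perm = rng.permutation(idx)
        der.append(perm[:n_sel])
        val.append(perm[n_sel:])
    return np.concatenate(der), np.concatenate(val)


def _statistic(
    X: np.ndarray, call_ctx: np.ndarray, groups: List[np.ndarray],
    ind_labels: np.ndarray, n_sel: int, k_sel: int, rng: np.random.Generator,
) -> Tuple[float, float]:
    """Mean (pct_classified, pct_cross) over ``k_sel`` balanced selections,
    with per-call context labels induced by the individual labelling."""
    y = ind_labels[call_ctx]
    acc, acc_cross, n_cross = 0.0, 0.0, 0
    for _ in range(k_sel):
        der, val = balanced_selection(groups, n_sel, rng)
        pct, pct_cross = classify_lda(X[der], y[der],
                                      X[val] if val.size else None,
                                      y[val] if val.size else None)
        acc += pct
        if pct_cross is not None:
            acc_cross += pct_cross
            n_cross += 1
    return acc / k_sel, (acc_cross / n_cross) if n_cross else np.nan


def nested_pdfa(
    features: pd.DataFrame,
    settings: Optional[PDFASettings] = None,
    feature_columns: Optional[Sequence[str]] = None,
) -> PDFAResult:
    """Permuted DFA for a two-context design with individuals nested in
    contexts.

    The observed classification percentages are averaged over balanced
    selections; the null distribution reassigns context labels to whole
    individuals uniformly among assignments preserving the per-context
    individual counts. p-values use the add-the-observed convention
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    settings = settings or PDFASettings()
    feature_columns = list(feature_columns or PARAMETER_COLUMNS)
    df = features.dropna(subset=feature_columns).reset_index(drop=True)
    n_dropped = len(features) - len(df)
    if n_dropped:
        logger.info("nested_pdfa: dropped %d calls with missing features", n_dropped)

    ctx_per_ind = df.groupby("individual_id")["context"].nunique()
    if (ctx_per_ind > 1).any():
        bad = ctx_per_ind[ctx_per_ind > 1].index.tolist()
        raise DataError(
            f"design is not nested; crossed pDFA not implemented "
            f"(individuals in several contexts: {bad})"
        )

    counts = df.groupby("individual_id").size()
    n_sel = settings.n_sel_calls or int(counts.min())
    excluded = counts.index[counts < n_sel].tolist()
    if excluded:
        logger.warning("nested_pdfa: excluding %d individuals with < %d calls: %s",
                       len(excluded), n_sel, excluded)
        df = df[~df["individual_id"].isin(excluded)].reset_index(drop=True)

    individuals = df["individual_id"].drop_duplicates().to_numpy()
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    call_ind = df["individual_id"].map(ind_index).to_numpy()
    groups = [np.flatnonzero(call_ind == i) for i in range(len(individuals))]
    true_ctx = (
        df.drop_duplicates("individual_id").set_index("individual_id")["context"]
        .loc[individuals].to_numpy()
    )
    levels = np.unique(true_ctx)
    if levels.size != 2:
        raise DataError(f"need exactly 2 contexts, got {levels.tolist()}")
    per_ctx = {lv: int((true_ctx == lv).sum()) for lv in levels}
    if min(per_ctx.values()) < 2:
        raise DataError(f"need >= 2 individuals per context, got {per_ctx}")

    X = df[feature_columns].to_numpy(dtype=float)
    ind_labels = (true_ctx == levels[1]).astype(int)

    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 404]))
    obs, obs_cross = _statistic(X, call_ind, groups, ind_labels, n_sel,
                                settings.k_selections_observed, rng)

    null = np.empty(settings.n_perm)
    null_cross = np.empty(settings.n_perm)
    for b in range(settings.n_perm):
        perm_labels = rng.permutation(ind_labels)
        null[b], null_cross[b] = _statistic(
            X, call_ind, groups, perm_labels, n_sel,
            settings.k_selections_perm, rng,
        )

    have_cross = np.isfinite(obs_cross) and np.isfinite(null_cross).all()
    p_cls = (1.0 + np.sum(null >= obs)) / (settings.n_perm + 1.0)
    chance_cross = float(null_cross.mean()) if have_cross else None
    result = PDFAResult(
        pct_classified=obs,
        pct_cross_classified=float(obs_cross) if have_cross else None,
        chance_classified=float(null.mean()),
        chance_cross_classified=chance_cross,
        relative_cross_classification=(
            float(obs_cross / chance_cross) if have_cross and chance_cross else None
        ),
        p_classified=float(p_cls),
        p_cross_classified=(
            float((1.0 + np.sum(null_cross >= obs_cross)) / (settings.n_perm + 1.0))
            if have_cross else None
        ),
        n_individuals=len(individuals),
        n_calls=len(df),
        excluded_individuals=excluded,
        settings={**asdict(settings), "n_sel_calls_effective": n_sel,
                  "contexts": levels.tolist()},
    )
    if not have_cross:
        logger.warning("nested_pdfa: empty validation set; cross-classification "
                       "statistics unavailable")
    return result


def format_pdfa_table(result: PDFAResult) -> str:
    """Human-readable summary mirroring the classification-result table."""
    def fmt(x, nd=2):
        return "NA" if x is None else f"{x:.{nd}f}"

    lines = [
        ("No. context categories", "2"),
        ("No. individuals", str(result.n_individuals)),
        ("Total no. calls", str(result.n_calls)),
        ("Correctly classified (%)", fmt(result.pct_classified)),
        ("Chance level (%)", fmt(result.chance_classified)),
        ("P value for classified", fmt(result.p_classified, 4)),
        ("Correctly cross-classified (%)", fmt(result.pct_cross_classified)),
        ("Chance level for cross-classified (%)", fmt(result.chance_cross_classified)),
        ("Relative cross-classification level", fmt(result.relative_cross_classification)),
        ("P value for cross-classified", fmt(result.p_cross_classified, 4)),
    ]
    width = max(len(k) for k, _ in lines) + 2
    return "\n".join(f"{k:<{width}}{v}" for k, v in lines)
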