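"""Performance metrics for AMSA estimators.

Error metrics between estimated values y_hat and true values y over N
segments:

    MAE  = mean |y - y_hat|
    RMSE = sqrt(mean (y - y_hat)^2)
    PRD  = sqrt( sum (y - y_hat)^2 / sum y^2 ) * 100 %

(percentage root-mean-square difference, normalised by the true values;
note PRD can exceed 100% for badly matched estimates).  Rank agreement is
Spearman's r (average ranks for ties).  Agreement structure is summarised
Bland-Altman style (bias and 1.96-SD limits of agreement of the
differences).  Discrimination of binary shock success by an AMSA score is
the ROC AUC via the Mann-Whitney identity with half-credit for ties, its
standard error by the Hanley-McNeil formula, and paired AUC comparison by
DeLong's method (default) or the Hanley-McNeil 1983 correlation-adjusted
z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class MetricsReport:
    """MAE/RMSE/PRD/Spearman bundle for one estimator on one dataset."""

    mae: float
    rmse: float
    prd: float
    spearman_r: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "rmse": self.rmse, "prd": self.prd,
                "spearman_r": self.spearman_r, "n": self.n}


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement of (estimate - truth) differences."""

    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class RocResult:
    """AUC with Hanley-McNeil standard error and the ROC curve points."""

    auc: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray
    scores: np.ndarray
    labels: np.ndarray


def compute_metrics(estimates, truths) -> MetricsReport:
    """MAE, RMSE, PRD and Spearman r of estimates against true values."""
    y_hat = np.asarray(estimates, dtype=float)
    y = np.asarray(truths, dtype=float)
    if y_hat.shape != y.shape or y.ndim != 1 or y.size == 0:
        raise InvalidInputError("estimates and truths must be equal-length 1-D vectors")
    err = y - y_hat
    denom = float(np.sum(y ** 2))
    if denom == 0.0:
        raise InvalidInputError("PRD undefined: true values are all zero")
    if y.size >= 2 and np.ptp(y) > 0 and np.ptp(y_hat) > 0:
        rho = float(_st.spearmanr(y_hat, y).statistic)
    else:
        rho = float("nan")  # undefined without variation in both vectors
    return MetricsReport(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        prd=float(np.sqrt(np.sum(err ** 2) / denom) * 100.0),
        spearman_r=rho,
        n=int(y.size),
    )


def bland_altman(estimates, truths) -> BlandAltman:
    """Bias and 1.96-SD limits of agreement of (estimate - truth)."""
    y_hat = np.asarray(estimates, dtype=float)
    y = np.asarray(truths, dtype=float)
    if y_hat.shape != y.shape or y.size < 3:
        raise InvalidInputError("Bland-Altman needs >= 3 paired observations")
    d = y_hat - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(scores, labels) -> RocResult:
    """ROC AUC by the Mann-Whitney identity (ties get half credit).

    The standard error follows Hanley & McNeil (1982).  Raises if only one
    class is present.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    if s.shape != lab.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be equal-length 1-D vectors")
    n_pos = int(np.sum(lab == 1))
    n_neg = int(np.sum(lab == 0))
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both outcome classes must be present")
    ranks = _st.rankdata(s)  # average ranks: ties get half credit in U
    u = float(np.sum(ranks[lab == 1])) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(lab[order] == 1)
    fps = np.cumsum(lab[order] == 0)
    keep = np.r_[np.flatnonzero(np.diff(s[order])), s.size - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return RocResult(auc=auc, se=_hanley_mcneil_se(auc, n_pos, n_neg),
                     fpr=fpr, tpr=tpr, scores=s, labels=lab)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # structural components: V10 over positives, V01 over negatives
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size for q in neg])
    return v10, v01


def compare_auc(r1: RocResult, r2: RocResult, method: str = "delong") -> tuple[float, float]:
    """Two-sided paired comparison of two AUCs on the same cases.

    Returns (z, p).  ``method='delong'`` uses the DeLong covariance of the
    paired structural components; ``method='hanley_mcneil'`` uses the 1983
    z-test with the score-correlation adjustment r approximated by the
    average within-class Pearson correlation of the two score vectors.
    """
    if not np.array_equal(r1.labels, r2.labels):
        raise InvalidInputError("paired AUC comparison requires identical cases/labels")
    a1, a2 = r1.auc, r2.auc
    if method == "delong":
        v10a, v01a = _delong_components(r1.scores, r1.labels)
        v10b, v01b = _delong_components(r2.scores, r2.labels)
        n_pos, n_neg = v10a.size, v01a.size
        s10 = np.cov(np.stack([v10a, v10b])) if n_pos > 1 else np.zeros((2, 2))
        s01 = np.cov(np.stack([v01a, v01b])) if n_neg > 1 else np.zeros((2, 2))
        cov = s10 / n_pos + s01 / n_neg
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    elif method == "hanley_mcneil":
        lab = r1.labels
        rs = []
        for cls in (0, 1):
            s1, s2 = r1.scores[lab == cls], r2.scores[lab == cls]
            if s1.size > 1 and np.std(s1) > 0 and np.std(s2) > 0:
                rs.append(float(np.corrcoef(s1, s2)[0, 1]))
        r = float(np.mean(rs)) if rs else 0.0
        var = r1.se ** 2 + r2.se ** 2 - 2 * r * r1.se * r2.se
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    if var <= 0:
        return 0.0, 1.0
    z = (a1 - a2) / np.sqrt(var)
    p = 2.0 * float(_st.norm.sf(abs(z)))
    return float(z), p


def plot_bland_altman(estimates, truths, ax=None):
    """Mean-difference plot with bias and limits-of-agreement lines."""
    import matplotlib.pyplot as plt

    ba = bland_altman(estimates, truths)
    y_hat = np.asarray(estimates, dtype=float)
    y = np.asarray(truths, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((y_hat + y) / 2.0, y_hat - y, s=12, alpha=0.6)
    for val, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(val, linestyle=style, color="gray")
    ax.set_xlabel("mean of estimate and truth (mV·Hz)")
    ax.set_ylabel("estimate − truth (mV·Hz)")
    return ax
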