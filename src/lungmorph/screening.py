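"""Pearson-correlation factor screening against the task label.

Each candidate factor is correlated with the (numeric-coded) label; factors
with |r| > 0.05 and p < 0.05 are retained.  The p-value comes from the exact
t-statistic r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom (two-sided).
Correlations are computed on the training partition only, at per-nucleus row
level by default (a patient-mean aggregation is available).  The factor-factor
correlation matrix is also produced, with highly collinear pairs (|r| > 0.8)
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .assemble import AssembledDataset

__all__ = [
    "CorrelationResult",
    "ScreeningReport",
    "pearson",
    "screen_factors",
]

R_CUTOFF = 0.05
P_CUTOFF = 0.05
HIGH_CORR = 0.8


class ConstantInputError(ValueError):
    """Raised when a correlation is undefined because an input is constant."""


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value for two equal-length vectors.

    r is the normalised cross-moment sum; p comes from the t-distribution with
    n-2 degrees of freedom.  Raises :class:`ConstantInputError` when either
    vector is constant (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    """Screening outcome for one factor."""

    factor: str
    r: float
    p: float
    retained: bool
    degenerate: bool = False
    high_corr_partners: list[str] = field(default_factory=list)


@dataclass
class ScreeningReport:
    """All per-factor results plus the factor-factor correlation matrix."""

    results: list[CorrelationResult]
    corr_matrix: pd.DataFrame
    label: str

    @property
    def retained(self) -> list[str]:
        return [r.factor for r in self.results if r.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "factor": r.factor, "r": r.r, "p": r.p, "retained": r.retained,
            "degenerate": r.degenerate,
            "high_corr_partners": ";".join(r.high_corr_partners),
        } for r in self.results])

    def save(self, outdir: str | Path, heatmap: bool = False) -> None:
        """Write the screening report and correlation matrix as CSV.

        With ``heatmap=True`` also renders the matrix as a PNG, marking
        |r| > 0.8 pairs with '+'.
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "screening.csv", index=False)
        self.corr_matrix.to_csv(out / "correlation_matrix.csv")
        if heatmap:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            m = self.corr_matrix.to_numpy(float)
            fig, ax = plt.subplots(
                figsize=(max(6, 0.25 * m.shape[0]),) * 2)
            im = ax.imshow(m, vmin=-1, vmax=1, cmap="coolwarm")
            ax.set_xticks(range(m.shape[0]))
            ax.set_xticklabels(self.corr_matrix.columns, rotation=90, fontsize=5)
            ax.set_yticks(range(m.shape[0]))
            ax.set_yticklabels(self.corr_matrix.index, fontsize=5)
            for i in range(m.shape[0]):
                for j in range(m.shape[1]):
                    if i != j and abs(m[i, j]) > HIGH_CORR:
                        ax.text(j, i, "+", ha="center", va="center", fontsize=5)
            fig.colorbar(im)
            fig.tight_layout()
            fig.savefig(out / "correlation_heatmap.png", dpi=150)
            plt.close(fig)


def screen_factors(dataset: AssembledDataset, label: str | None = None,
                   part: str = "train", r_cutoff: float = R_CUTOFF,
                   p_cutoff: float = P_CUTOFF,
                   aggregate_patients: bool = False) -> ScreeningReport:
    """Screen every design-matrix factor against the task label.

    Retention requires |r| > ``r_cutoff`` and p < ``p_cutoff``.  Constant
    factors are reported as non-retained with the degenerate flag rather than
    dropped silently.  ``aggregate_patients=True`` computes correlations on
    patient-mean rows instead of per-nucleus rows.
    """
    label = label or dataset.label_column
    sub = dataset.subset(part)
    if aggregate_patients:
        sub = sub.groupby("patient_id")[
            dataset.feature_columns + [label]].mean().reset_index()
    y = sub[label].to_numpy(float)
    results = []
    cols = dataset.feature_columns
    mat = sub[cols].to_numpy(float)
    # factor-factor correlation matrix (constant columns yield NaN rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(mat, rowvar=False)
    corr_matrix = pd.DataFrame(cm, index=cols, columns=cols)
    for j, col in enumerate(cols):
        x = mat[:, j]
        try:
            r, p = pearson(x, y)
            retained = abs(r) > r_cutoff and p < p_cutoff
            degenerate = False
        except ConstantInputError:
            r, p, retained, degenerate = float("nan"), float("nan"), False, True
        partners = [c for i, c in enumerate(cols)
                    if i != j and abs(cm[j, i]) > HIGH_CORR]
        results.append(CorrelationResult(factor=col, r=r, p=p,
                                         retained=retained,
                                         degenerate=degenerate,
                                         high_corr_partners=partners))
    return ScreeningReport(results=results, corr_matrix=corr_matrix, label=label)
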