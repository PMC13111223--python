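"""Cross-subject correlation of field metrics with connectivity strengths.

Pearson r with the two-sided p-value from the exact t transform
t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, significance at
alpha = 0.05, no multiplicity adjustment (a Bonferroni column is emitted
alongside for transparency). A seeded permutation p-value is available for
small-n robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

ALPHA = 0.05


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    p_two_sided: float
    significant: bool

    def as_dict(self) -> dict:
        return {"x": self.x_name, "y": self.y_name, "n": self.n,
                "r": self.r, "p": self.p_two_sided,
                "significant": self.significant}


def pearson(x, y, x_name: str = "x", y_name: str = "y",
            method: str = "t", n_permutations: int = 10_000,
            seed: int | None = None) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided p-value.

    ``method='t'`` uses the exact t reference distribution;
    ``method='permutation'`` shuffles y (seeded) and reports the fraction
    of |r| at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = sstats.pearsonr(x, y)
    r = float(r)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        perms = np.array([
            abs(xc @ rng.permutation(yc)) / denom
            for _ in range(n_permutations)
        ])
        p = float((1 + (perms >= abs(r) - 1e-15).sum()) / (1 + n_permutations))
    elif method != "t":
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(x_name, y_name, n, r, float(p), bool(p < ALPHA))


def correlate_cohort(table: pd.DataFrame, pairs: list,
                     method: str = "t", seed: int | None = None,
                     on_degenerate: str = "raise") -> pd.DataFrame:
    """One Pearson correlation per (EF column, SC-edge column) pair.

    No multiple-comparison correction is applied to the primary p (the
    few-edges-tested convention); a Bonferroni-adjusted column is included.
    ``on_degenerate='record'`` turns a zero-variance column into an
    r = NaN, non-significant row instead of an error (used by the pipeline,
    where e.g. an exactly isotropic cohort makes every DTI metric constant).
    """
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in cohort table")
    results = []
    for xcol, ycol in pairs:
        for c in (xcol, ycol):
            if c not in table.columns:
                raise ValueError(f"column {c!r} missing from cohort table")
        x = table[xcol].to_numpy(dtype=float)
        y = table[ycol].to_numpy(dtype=float)
        if on_degenerate == "record" and (np.std(x) == 0 or np.std(y) == 0):
            results.append({"x": xcol, "y": ycol, "n": len(x),
                            "r": np.nan, "p": np.nan, "significant": False})
            continue
        res = pearson(x, y, x_name=xcol, y_name=ycol, method=method,
                      seed=seed)
        results.append(res.as_dict())
    out = pd.DataFrame(results)
    out["p_bonferroni"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out


def fisher_z_interval(r: float, n: int, level: float = 0.95) -> tuple:
    """Fisher-z confidence interval for a correlation coefficient."""
    if not -1 < r < 1:
        raise ValueError("r must lie strictly inside (-1, 1)")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sstats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))
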