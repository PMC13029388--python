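"""Alpha-diversity panel and mother/daughter (PM vs PF) rank-sum contrasts.

Indices computed per sample from raw integer counts: observed richness,
bias-corrected Chao1, ACE (rare threshold 10), Shannon (natural log),
Gini-Simpson (1 - sum p^2), inverse Simpson, Fisher's alpha and Pielou
evenness (Shannon / ln S_obs).  Chao1, ACE and Fisher's alpha rely on
singleton/doubleton structure and are therefore undefined on relative
abundances — non-integer input is rejected.

No rarefaction is applied; the library size is carried as a covariate so
downstream users can condition on it.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import mannwhitneyu
from skbio.diversity.alpha import ace, chao1, pielou_e, shannon, simpson

from vinherit.core_io import CommunityTable, ValidationError

ALPHA_INDICES = (
    "observed_richness",
    "chao1",
    "ace",
    "shannon",
    "simpson",
    "inv_simpson",
    "fisher_alpha",
    "pielou",
)


def fisher_alpha(counts: np.ndarray, tol: float = 1e-10) -> float:
    """Fisher's alpha: the root of ``S = alpha * ln(1 + N / alpha)``.

    Solved by bracketed root-finding (Brent); the bracket is grown until
    it encloses the root.
    """
    counts = np.asarray(counts)
    S = int((counts > 0).sum())
    N = int(counts.sum())
    if S <= 0 or N <= 0:
        return math.nan
    if S == N:
        return math.inf  # all singletons: the defining equation has no finite root

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    return float(brentq(f, lo, hi, xtol=tol))


def alpha_panel(table: CommunityTable) -> pd.DataFrame:
    """One row of diversity indices per sample.

    Empty samples yield a row of NaNs with ``undefined=True`` rather than
    an exception, so a sparse stratum never aborts a run.
    """
    if not np.issubdtype(table.counts.dtype, np.integer):
        raise ValidationError(
            "alpha diversity requires integer counts (Chao1/ACE/Fisher are "
            "undefined on relative abundances)"
        )
    rows = []
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        c = c[c > 0]
        if c.size == 0:
            rows.append({"sample_id": sid, "library_size": 0, "undefined": True,
                         **{k: math.nan for k in ALPHA_INDICES}})
            continue
        sobs = int(c.size)
        p = c / c.sum()
        sh = float(shannon(c, base=math.e))
        rows.append({
            "sample_id": sid,
            "library_size": int(c.sum()),
            "undefined": False,
            "observed_richness": sobs,
            "chao1": float(chao1(c, bias_corrected=True)),
            "ace": float(ace(c, rare_threshold=10)),
            "shannon": sh,
            "simpson": float(simpson(c)),                 # Gini-Simpson, 1 - sum p^2
            "inv_simpson": float(1.0 / np.sum(p**2)),
            "fisher_alpha": fisher_alpha(c),
            "pielou": float(pielou_e(c)) if sobs > 1 else math.nan,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def _ranksum(pm: np.ndarray, pf: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney: exact for n <= 20 without ties, else normal
    approximation with tie correction."""
    has_ties = len(np.unique(np.concatenate([pm, pf]))) < len(pm) + len(pf)
    method = "exact" if (max(len(pm), len(pf)) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(pm, pf, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_generations(
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    stratum_by: tuple[str, ...] = ("chateau", "compartment"),
    indices: tuple[str, ...] = ALPHA_INDICES,
) -> pd.DataFrame:
    """Wilcoxon rank-sum PM-vs-PF contrast per index per stratum.

    Strata missing a generation, or with a single sample in one, are
    reported as NA rows with a warning instead of failing the run.
    """
    meta = metadata.loc[records.index]
    rows = []
    for key, grp in meta.groupby(list(stratum_by), observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        pm_ids = grp.index[grp["generation"] == "PM"]
        pf_ids = grp.index[grp["generation"] == "PF"]
        if len(pm_ids) == 0 or len(pf_ids) == 0:
            warnings.warn(f"stratum {key}: a generation is absent, skipped", stacklevel=2)
            continue
        for index in indices:
            pm = records.loc[pm_ids, index].dropna().to_numpy(dtype=float)
            pf = records.loc[pf_ids, index].dropna().to_numpy(dtype=float)
            base = dict(zip(stratum_by, key), index=index, n_pm=len(pm), n_pf=len(pf))
            if len(pm) < 2 or len(pf) < 2:
                warnings.warn(f"stratum {key}: fewer than 2 samples per generation "
                              f"for {index!r}", stacklevel=2)
                rows.append({**base, "statistic": math.nan, "p_value": math.nan,
                             "higher_in": "NA"})
                continue
            stat, p = _ranksum(pm, pf)
            higher = "PM" if np.median(pm) > np.median(pf) else (
                "PF" if np.median(pf) > np.median(pm) else "tie")
            rows.append({**base, "statistic": stat, "p_value": p, "higher_in": higher})
    return pd.DataFrame(rows)
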