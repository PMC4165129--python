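"""qPCR relative quantification: efficiency, NRQ, geNORM, ANOVA/LSD.

The chain mirrors standard SYBR-green workflow practice: per-reaction
amplification efficiency from the window of linearity of the log-linear
phase, plate-average efficiency, normalised relative quantities (NRQ)
against the geometric mean of reference genes, geNORM reference-gene
stability (M values and the pairwise-variation ladder V_{n/n+1}), mean
centering for merging runs, and one-way ANOVA with Fisher's protected LSD
on log-transformed quantities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrWell",
    "NrqTable",
    "GenormResult",
    "AnovaLsdResult",
    "efficiency_window_of_linearity",
    "plate_mean_efficiency",
    "compute_nrq",
    "genorm",
    "mean_center_combine",
    "anova_lsd",
    "wells_to_frame",
]


@dataclass
class QpcrWell:
    """One qPCR reaction: labels, quantification cycle, optional raw curve."""

    sample: str
    gene: str
    replicate: int
    cq: float | None
    curve: np.ndarray | None = None  # (n_cycles, 2): cycle, fluorescence

    def __post_init__(self) -> None:
        if self.cq is not None and self.cq <= 0:
            raise ValueError(f"cq must be positive, got {self.cq}")
        if self.curve is not None:
            self.curve = np.asarray(self.curve, dtype=float)
            if self.curve.ndim != 2 or self.curve.shape[1] != 2:
                raise ValueError("curve must be an (n, 2) array of (cycle, fluorescence)")


def wells_to_frame(wells: list[QpcrWell]) -> pd.DataFrame:
    """Well labels and Cq values as a tidy DataFrame."""
    return pd.DataFrame(
        [{"sample": w.sample, "gene": w.gene, "replicate": w.replicate, "cq": w.cq} for w in wells]
    )


# -- amplification efficiency ---------------------------------------------

def efficiency_window_of_linearity(
    curve,
    window_sizes=(4, 5, 6),
    r2_threshold: float = 0.995,
    baseline_cycles: int = 5,
    plateau_fraction: float = 0.9,
) -> float:
    """Per-cycle amplification base from the log-linear window of a curve.

    The baseline (mean fluorescence of the first ``baseline_cycles`` cycles)
    is subtracted and candidate points are those clearly above baseline
    noise and below ``plateau_fraction`` of the maximum.  Fluorescence is
    linearised as ``log10(F / (1 - F/P))`` with ``P`` the observed plateau
    — the plain log of a saturating amplification curve curves downward,
    and this first-order correction removes that bias — and the contiguous
    window of 4-6 cycles with the highest R^2 is selected, ties going to
    the lowest-fluorescence window, where exponential growth is purest.
    Returns ``10**slope`` of the fit on the selected window.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or len(curve) < 10:
        raise ValueError("curve must be an (n >= 10, 2) array of (cycle, fluorescence)")
    cyc = curve[:, 0]
    f = curve[:, 1]
    baseline = f[:baseline_cycles].mean()
    noise = f[:baseline_cycles].std(ddof=1)
    fs = f - baseline
    m = fs.max()
    if m <= 0:
        raise ValueError("no exponential phase: curve never rises above baseline")
    lo_thresh = max(10.0 * noise, 1e-12 * max(1.0, m))
    usable = (fs > lo_thresh) & (fs < plateau_fraction * m)
    idx = np.flatnonzero(usable)
    p_hat = m * (1.0 + 1e-9)
    best = None  # ((r2, -mean_f, w), window, slope)
    for w in window_sizes:
        for start in range(len(idx) - w + 1):
            sel = idx[start : start + w]
            if sel[-1] - sel[0] != w - 1:  # require consecutive cycles
                continue
            y = np.log10(fs[sel] / (1.0 - fs[sel] / p_hat))
            x = cyc[sel]
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
            key = (round(r2, 12), -fs[sel].mean(), w)
            if best is None or key > best[0]:
                best = (key, sel, slope)
    if best is None or best[0][0] < r2_threshold:
        raise ValueError("no exponential phase: no window reaches the R^2 threshold")
    eff = 10.0 ** best[2]
    if eff <= 1.0:
        raise ValueError("no exponential phase: non-positive amplification slope")
    return float(eff)


def plate_mean_efficiency(efficiencies) -> float:
    """Arithmetic mean efficiency of all reactions on a plate."""
    eff = np.asarray([e for e in efficiencies if np.isfinite(e)], dtype=float)
    if eff.size == 0:
        raise ValueError("no finite efficiencies supplied")
    return float(eff.mean())


# -- normalised relative quantities ----------------------------------------

@dataclass
class NrqTable:
    """Normalised relative quantities per sample x gene."""

    nrq: pd.DataFrame  # samples x genes
    normalization_factor: pd.Series  # per sample
    efficiency: dict  # per gene
    rq: pd.DataFrame  # pre-normalisation relative quantities


def compute_nrq(wells, reference_genes, efficiency_per_gene) -> NrqTable:
    """Efficiency-corrected relative quantities, normalised to reference genes.

    Technical replicates are averaged on the Cq scale; per gene, the relative
    quantity of a sample is ``E ** (mean_Cq_gene - Cq_sample)`` (centred on
    the across-sample mean Cq, so ratios between samples are unaffected by
    the calibrator choice); the normalisation factor of a sample is the
    geometric mean of its reference-gene relative quantities.
    """
    df = wells if isinstance(wells, pd.DataFrame) else wells_to_frame(wells)
    if df["cq"].isna().any():
        missing = df.loc[df["cq"].isna(), ["sample", "gene"]].iloc[0]
        raise ValueError(f"missing Cq for sample {missing['sample']!r}, gene {missing['gene']!r}")
    cq = df.groupby(["sample", "gene"])["cq"].mean().unstack("gene")
    for ref in reference_genes:
        if ref not in cq.columns:
            raise ValueError(f"reference gene {ref!r} has no wells")
        bad = cq.index[cq[ref].isna()]
        if len(bad):
            raise ValueError(f"sample {bad[0]!r} lacks a Cq for reference gene {ref!r}")
    eff = {g: float(efficiency_per_gene[g]) if not np.isscalar(efficiency_per_gene)
           else float(efficiency_per_gene) for g in cq.columns}
    for g, e in eff.items():
        if e <= 1.0:
            raise ValueError(f"efficiency for gene {g!r} must exceed 1, got {e}")
    rq = pd.DataFrame(index=cq.index, columns=cq.columns, dtype=float)
    for g in cq.columns:
        rq[g] = eff[g] ** (cq[g].mean() - cq[g])
    nf = np.exp(np.log(rq[list(reference_genes)]).mean(axis=1))
    nrq = rq.div(nf, axis=0)
    return NrqTable(nrq=nrq, normalization_factor=nf, efficiency=eff, rq=rq)


# -- geNORM ----------------------------------------------------------------

@dataclass
class GenormResult:
    """Reference-gene stability: M values, stability ranking, V ladder."""

    M: pd.Series  # stability of each gene over the full candidate set
    ranking: list  # genes from most to least stable
    V: dict  # {"V2/3": ..., "V3/4": ...}


def _m_values(logq: pd.DataFrame) -> pd.Series:
    genes = list(logq.columns)
    out = {}
    for g in genes:
        sds = [logq[g].sub(logq[h]).std(ddof=1) for h in genes if h != g]
        out[g] = float(np.mean(sds))
    return pd.Series(out)


def genorm(quantities: pd.DataFrame) -> GenormResult:
    """geNORM stability analysis of candidate reference genes.

    ``quantities`` is a samples x genes table of positive relative
    quantities.  A gene's stability M is the mean, over all other genes, of
    the standard deviation across samples of the pairwise log2 ratio; genes
    are ranked by iteratively excluding the least stable one.  The pairwise
    variation ``V_{n/n+1}`` is the SD across samples of
    ``log2(NF_n / NF_{n+1})`` with ``NF_k`` the geometric mean of the ``k``
    most stable genes, and indicates whether adding the (n+1)-th reference
    gene still changes the normalisation factor appreciably.
    """
    q = quantities.astype(float)
    if (q <= 0).any().any():
        raise ValueError("all quantities must be positive")
    if q.shape[1] < 3 or q.shape[0] < 2:
        raise ValueError("need at least 3 candidate genes and 2 samples")
    logq = np.log2(q)
    m_full = _m_values(logq)
    remaining = list(q.columns)
    least_stable: list = []
    while len(remaining) > 2:
        m = _m_values(logq[remaining])
        worst = m.idxmax()
        least_stable.append(worst)
        remaining.remove(worst)
    ranking = remaining + least_stable[::-1]
    v = {}
    for k in range(2, q.shape[1]):
        nf_k = logq[ranking[:k]].mean(axis=1)
        nf_k1 = logq[ranking[: k + 1]].mean(axis=1)
        v[f"V{k}/{k + 1}"] = float((nf_k - nf_k1).std(ddof=1))
    return GenormResult(M=m_full, ranking=ranking, V=v)


# -- run merging -----------------------------------------------------------

def mean_center_combine(datasets: list[pd.DataFrame], log_base: float = 2.0) -> pd.DataFrame:
    """Merge NRQ tables from separate runs after per-run mean centering.

    Each dataset (samples x genes, positive NRQs, same gene set, disjoint
    samples) is log-transformed and each gene centred on its within-run
    mean, removing run-level offsets; the centred tables are concatenated.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    genes = set(datasets[0].columns)
    for d in datasets[1:]:
        if set(d.columns) != genes:
            raise ValueError("datasets must share an identical gene set")
    seen: set = set()
    for d in datasets:
        overlap = seen & set(d.index)
        if overlap:
            raise ValueError(f"datasets must have disjoint samples; shared: {sorted(overlap)}")
        seen |= set(d.index)
    centred = []
    for d in datasets:
        logd = np.log(d.astype(float)) / np.log(log_base)
        centred.append(logd - logd.mean(axis=0))
    return pd.concat(centred, axis=0)


# -- ANOVA with protected LSD ---------------------------------------------

@dataclass
class AnovaLsdResult:
    """One-way ANOVA with Fisher's protected LSD and letter display."""

    f_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # group1, group2, diff, t, p, different
    letters: dict  # group -> compact letters


def _compact_letters(groups: list, means: dict, different: set) -> dict:
    """Insert-and-absorb compact letter display."""
    sets: list[set] = [set(groups)]
    for i, j in different:
        for s in [s for s in sets if i in s and j in s]:
            sets.remove(s)
            for new in (s - {i}, s - {j}):
                if new and not any(new <= other for other in sets):
                    sets.append(new)
            sets = [s2 for s2 in sets if not any(s2 < other for other in sets)]
    order = sorted(groups, key=lambda g: -means[g])
    ranked = sorted(sets, key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", ranked):
        for g in s:
            letters[g] += letter
    return letters


def anova_lsd(values, groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA followed by Fisher's protected LSD.

    Pairwise comparisons use t statistics on the pooled within-group mean
    square (df = N - k) and are only declared when the omnibus F test is
    significant at ``alpha``; the compact-letter display then groups
    statistically indistinguishable levels under a shared letter.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: values[groups == g] for g in levels}
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    f_stat, p_omni = stats.f_oneway(*[by[g] for g in levels])
    n_tot = len(values)
    k = len(levels)
    df_err = n_tot - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / df_err
    means = {g: float(v.mean()) for g, v in by.items()}
    rows = []
    different: set = set()
    protected = p_omni < alpha
    for g1, g2 in itertools.combinations(levels, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(mse * (1.0 / len(by[g1]) + 1.0 / len(by[g2])))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p = 2.0 * stats.t.sf(abs(t), df_err)
        # protection: no pair is declared different unless the omnibus F is
        is_diff = protected and p < alpha
        if is_diff:
            different.add((g1, g2))
        rows.append(
            {"group1": g1, "group2": g2, "diff": diff, "t": t, "p": p, "different": is_diff}
        )
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "diff", "t", "p", "different"])
    letters = _compact_letters(levels, means, different)
    return AnovaLsdResult(
        f_statistic=float(f_stat), p_omnibus=float(p_omni), pairwise=pairwise, letters=letters
    )
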