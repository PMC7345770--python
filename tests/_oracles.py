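"""Independent reference implementations used only to check tinvmark.

Everything here is deliberately written as plain loops / closed forms,
not via the code paths (or library calls) the package itself uses.
"""

from __future__ import annotations

import math

from scipy import stats as _st  # only for the t CDF in the Welch oracle


def welch_t_p(x, y) -> tuple[float, float]:
    """Textbook Welch t statistic with Welch-Satterthwaite df; two-sided p."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * _st.t.sf(abs(t), df)
    return t, p


def pair_count_auc(labels, scores, positive="NGHC") -> float:
    """Mann-Whitney AUC: concordant (pos, neg) pairs + half ties, exhaustively."""
    pos = [s for lab, s in zip(labels, scores) if lab == positive]
    neg = [s for lab, s in zip(labels, scores) if lab != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def quantile_linear(values, q) -> float:
    """Sort-and-interpolate quantile (linear / 'type 7' rule)."""
    xs = sorted(float(v) for v in values)
    if len(xs) == 1:
        return xs[0]
    pos = q * (len(xs) - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def median(values) -> float:
    return quantile_linear(values, 0.5)


def iqr(values) -> float:
    return quantile_linear(values, 0.75) - quantile_linear(values, 0.25)


def cv_percent(values) -> float:
    """Two-pass sample-sd coefficient of variation, in percent."""
    xs = [float(v) for v in values]
    if len(xs) < 2:
        return 0.0
    m = sum(xs) / len(xs)
    sd = math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))
    return 100.0 * sd / m


def hypergeom_tail(k, n_universe, n_term, n_query) -> float:
    """P(overlap >= k) as an exhaustive sum of hypergeometric point masses."""
    total = 0.0
    denom = math.comb(n_universe, n_query)
    upper = min(n_term, n_query)
    for i in range(k, upper + 1):
        total += (
            math.comb(n_term, i)
            * math.comb(n_universe - n_term, n_query - i)
            / denom
        )
    return total


def consensus_scan(deg_tables, min_datasets=None):
    """Per-gene exhaustive scan for the consensus rule.

    Returns {gene: direction} for genes that are DEGs in >= min_datasets
    tables with a single direction among all tables where they are DEGs.
    """
    need = len(deg_tables) if min_datasets is None else min_datasets
    genes = set()
    for tab in deg_tables:
        genes |= set(tab.index)
    out = {}
    for gene in genes:
        dirs = []
        for tab in deg_tables:
            if gene in tab.index and bool(tab.at[gene, "is_deg"]):
                dirs.append(tab.at[gene, "direction"])
        if len(dirs) >= need and len(set(dirs)) == 1:
            out[gene] = dirs[0]
    return out
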