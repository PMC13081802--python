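"""Condition comparison of flux matrices.

Per-reaction and per-metabolite differential statistics (pooled-variance
two-tailed Student's t, Benjamini–Hochberg FDR, log2 fold change on
magnitudes with a pseudo-count), and subsystem enrichment of the
significant reactions by a one-sided Fisher's exact test against the whole
network as background.  BH adjustment is applied separately within the
three families (reactions, metabolites, subsystems).

Metabolite-level scores are production turnovers: for metabolite m and flux
column v, turnover(m) = Σ_j max(S_mj · v_j, 0) — the total production flux,
which at steady state equals total consumption.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "bh_adjust",
    "fisher_exact_2x2",
    "differential_reactions",
    "metabolite_turnover",
    "differential_metabolites",
    "subsystem_enrichment",
]

DIFF_COLUMNS = [
    "feature_id",
    "mean_ctrl",
    "mean_treat",
    "log2FC",
    "t",
    "p",
    "p_adj",
    "sign_flip",
    "degenerate_variance",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving.

    Sorts the m p-values, multiplies the i-th smallest by m/i, enforces
    monotonicity from the largest rank downwards, caps at 1 and restores
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher's exact test p-value for the 2×2 table [[a, b], [c, d]].

    ``greater`` is the hypergeometric upper tail P(X >= a) with margins
    fixed; ``two-sided`` sums the probabilities of all tables no more
    likely than the observed one.  Degenerate margins give p = 1.
    """
    counts = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    if sum(counts) == 0:
        raise ValueError("at least one count must be positive")
    a, b, c, d = (int(x) for x in counts)
    N, K, n = a + b + c + d, a + b, a + c
    rv = stats.hypergeom(N, K, n)
    if alternative == "greater":
        return float(min(1.0, rv.sf(a - 1)))
    if alternative == "two-sided":
        support = np.arange(max(0, K + n - N), min(K, n) + 1)
        pmf = rv.pmf(support)
        observed = rv.pmf(a)
        return float(min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


def _pooled_t(ctrl: np.ndarray, treat: np.ndarray) -> tuple[float, float, bool]:
    """Pooled-variance Student's t (treat − ctrl) and two-tailed p.

    Zero pooled variance is resolved deterministically: equal means give
    (0, 1), unequal means give (±inf, 0) with a degenerate-variance flag.
    """
    n1, n2 = len(ctrl), len(treat)
    diff = treat.mean() - ctrl.mean()
    df = n1 + n2 - 2
    pooled_var = (ctrl.var(ddof=1) * (n1 - 1) + treat.var(ddof=1) * (n2 - 1)) / df
    se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    if se == 0 or not np.isfinite(se):
        if diff == 0:
            return 0.0, 1.0, True
        return float(np.sign(diff) * np.inf), 0.0, True
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), False


def _group_values(matrix: pd.DataFrame, label: str) -> np.ndarray:
    if label not in matrix.columns.get_level_values("condition"):
        raise ValueError(f"condition {label!r} not present in flux matrix")
    values = matrix.xs(label, axis=1, level="condition").to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError(f"condition {label!r} has < 2 replicates")
    return values


def _differential_table(
    matrix: pd.DataFrame, ctrl_label: str, treat_label: str, epsilon: float
) -> pd.DataFrame:
    ctrl = _group_values(matrix, ctrl_label)
    treat = _group_values(matrix, treat_label)
    records = []
    for i, fid in enumerate(matrix.index):
        t, p, degenerate = _pooled_t(ctrl[i], treat[i])
        mc, mt = float(ctrl[i].mean()), float(treat[i].mean())
        log2fc = float(np.log2((abs(mt) + epsilon) / (abs(mc) + epsilon)))
        sign_flip = mc * mt < 0
        records.append((fid, mc, mt, log2fc, t, p, np.nan, sign_flip, degenerate))
    df = pd.DataFrame(records, columns=DIFF_COLUMNS)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def differential_reactions(
    flux_matrix: pd.DataFrame,
    ctrl_label: str,
    treat_label: str,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-reaction differential flux statistics between two conditions.

    Returns one row per reaction with group means, magnitude log2FC
    (pseudo-count ``epsilon``; ``sign_flip`` marks means of opposite sign),
    pooled t, two-tailed p (df = n1 + n2 − 2) and BH-adjusted p across all
    reactions.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return _differential_table(flux_matrix, ctrl_label, treat_label, epsilon)


def metabolite_turnover(
    network: MetabolicNetwork, flux_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Production turnover per metabolite and flux column.

    turnover(m, col) = Σ_j max(S_mj · v_j, 0); rows are metabolite ids,
    columns mirror the flux matrix.
    """
    unknown = set(flux_matrix.index) - set(network.reaction_ids)
    if unknown:
        raise ValueError(f"flux matrix rows not in network: {sorted(unknown)}")
    sm = stoichiometric_matrix(network)
    aligned = flux_matrix.reindex(list(sm.col_ids)).fillna(0.0)
    V = aligned.to_numpy(dtype=float)  # reactions × columns
    S = sm.S.toarray()  # metabolites × reactions
    production = np.maximum(S[:, :, None] * V[None, :, :], 0.0).sum(axis=1)
    return pd.DataFrame(
        production, index=pd.Index(sm.row_ids, name="metabolite_id"),
        columns=flux_matrix.columns,
    )


def differential_metabolites(
    network: MetabolicNetwork,
    flux_matrix: pd.DataFrame,
    ctrl_label: str,
    treat_label: str,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Differential statistics on metabolite production turnovers.

    Same machinery as :func:`differential_reactions`; BH is applied within
    the metabolite family.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    turnover = metabolite_turnover(network, flux_matrix)
    return _differential_table(turnover, ctrl_label, treat_label, epsilon)


def subsystem_enrichment(
    diff_table: pd.DataFrame,
    network: MetabolicNetwork,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Subsystem enrichment of significantly altered reactions.

    Reactions with p_adj < ``alpha`` form the significant set; each
    subsystem is tested with Fisher's exact test on the 2×2 table of
    significance × membership over the whole network background, and the
    per-subsystem p-values are BH-adjusted.
    """
    table = diff_table.set_index("feature_id")
    missing = set(network.reaction_ids) - set(table.index)
    if missing:
        raise ValueError(
            f"differential table must cover all network reactions; missing {sorted(missing)}"
        )
    significant = {
        rid for rid in network.reaction_ids if table.loc[rid, "p_adj"] < alpha
    }
    subsystems = sorted({r.subsystem for r in network.reactions if r.subsystem})
    blank = [r.id for r in network.reactions if not r.subsystem]
    if blank:
        warnings.warn(f"reactions without subsystem excluded from membership: {blank}")
    records = []
    n_total = len(network.reactions)
    for sub in subsystems:
        members = {r.id for r in network.reactions if r.subsystem == sub}
        a = len(members & significant)
        b = len(significant) - a
        c = len(members) - a
        d = n_total - a - b - c
        if a * d > 0 and b * c == 0:
            odds = float("inf")
        elif b * c == 0:
            odds = float("nan")
        else:
            odds = a * d / (b * c)
        p = fisher_exact_2x2(a, b, c, d, alternative=alternative)
        records.append((sub, a, b, c, d, odds, p))
    df = pd.DataFrame(
        records,
        columns=["subsystem", "k_sig_in", "k_sig_out", "k_nonsig_in", "k_nonsig_out",
                 "odds_ratio", "p"],
    )
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df
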