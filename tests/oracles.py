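"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, direct summation,
double loops) and shares no code with the package's own computation paths.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb

import numpy as np

from lipoflux.network import MetabolicNetwork, stoichiometric_matrix


def bh_stepup_bruteforce(p_values) -> np.ndarray:
    """Literal BH step-up: sort, scale by m/i, running min from the top."""
    p = list(map(float, p_values))
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return np.array(adjusted)


def hypergeom_tail_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the hypergeometric with margins of [[a,b],[c,d]]."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = comb(N, n)
    total = 0
    for x in range(a, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def fba_by_vertex_enumeration(network: MetabolicNetwork, tol: float = 1e-8):
    """LP optimum via exhaustive vertex enumeration of the flux polytope.

    Every vertex of {v : S v = 0, lb <= v <= ub} (bounded, since all
    bounds are finite) fixes at least n - rank(S) fluxes at a bound; we
    enumerate all such index subsets and bound assignments, solve for the
    remaining fluxes, and keep feasible solutions.  Returns the maximal
    objective value, or None if no feasible vertex exists.
    """
    sm = stoichiometric_matrix(network)
    S = sm.S.toarray()
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    n = S.shape[1]
    c = np.zeros(n)
    c[list(sm.col_ids).index(network.objective_id)] = 1.0
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    best = None
    for fixed in combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue
        for choice in product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.empty(n)
            v[list(fixed)] = choice
            rhs = -S[:, list(fixed)] @ np.array(choice) if fixed else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def association_bruteforce(dars, genes, class_of, promoter_bp=3000, downstream_bp=3000):
    """Double-loop re-implementation of the stratified association table.

    Returns {(gene_class, region, direction): (n_genes, n_with_dar)}.
    """
    regions = ("promoter", "gene_body", "downstream")

    def window(g, region):
        if region == "gene_body":
            return g.start, g.end
        upstream = g.strand == "+"
        if region == "downstream":
            upstream = not upstream
        if upstream:
            return max(0, g.start - (promoter_bp if region == "promoter" else downstream_bp)), g.start
        return g.end, g.end + (promoter_bp if region == "promoter" else downstream_bp)

    hit = {}
    for g in genes:
        for dar in dars:
            if dar.chrom != g.chrom:
                continue
            assigned = None
            for region in regions:
                lo, hi = window(g, region)
                if dar.start < hi and lo < dar.end:
                    assigned = region
                    break
            if assigned is not None:
                hit.setdefault((class_of[g.gene_id], assigned, dar.direction), set()).add(
                    g.gene_id
                )
    sizes = {}
    for g in genes:
        sizes[class_of[g.gene_id]] = sizes.get(class_of[g.gene_id], 0) + 1
    out = {}
    for cls in ("Up", "Down", "Unchanged"):
        for region in regions:
            for direction in ("Up", "Down"):
                out[(cls, region, direction)] = (
                    sizes.get(cls, 0),
                    len(hit.get((cls, region, direction), set())),
                )
    return out
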