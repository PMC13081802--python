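"""Condition-specific model construction: expression, kcat, ΔG′°, medium.

Each operation returns a *new* network with tightened bounds; inputs are
never mutated and every operation is idempotent.

* ``capacity_bounds`` caps |flux| at σ·kcat·a where a is the reaction-level
  enzyme abundance aggregated from transcript abundances over the GPR rule
  (AND = min over complex subunits, OR = sum over isoenzymes).
* ``thermodynamic_directions`` makes reactions with strongly negative ΔG′°
  forward-only and strongly positive ΔG′° reverse-only, with a dead band of
  ±τ kJ·mol⁻¹ around equilibrium.
* ``apply_medium`` opens uptake (negative exchange flux) only for
  metabolites present in the medium table; secretion stays free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .gpr import GPRTree
from .network import MetabolicNetwork, ReactionRecord

__all__ = [
    "ExpressionProfile",
    "MediumTable",
    "ConstraintConfig",
    "aggregate_gpr_abundance",
    "capacity_bounds",
    "thermodynamic_directions",
    "apply_medium",
    "attach_annotations",
    "read_expression_tsv",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_medium_tsv",
    "read_annotation_tsv",
    "read_config",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """One replicate's normalized transcript abundances (TPM-like, >= 0)."""

    condition: str
    replicate: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for gene, a in self.values.items():
            if not math.isfinite(a) or a < 0:
                raise ValueError(f"abundance for {gene!r} must be finite and >= 0, got {a}")


@dataclass(frozen=True)
class MediumTable:
    """Map metabolite id -> maximum uptake rate (mmol·gDW⁻¹·h⁻¹, >= 0).

    ``None`` entries take :attr:`ConstraintConfig.default_uptake`.
    """

    entries: dict[str, float | None]

    def __post_init__(self) -> None:
        for mid, rate in self.entries.items():
            if rate is not None and (not math.isfinite(rate) or rate < 0):
                raise ValueError(f"uptake for {mid!r} must be finite and >= 0, got {rate}")


@dataclass(frozen=True)
class ConstraintConfig:
    """Free parameters of model construction.

    capacity_scale (σ) converts kcat·abundance to flux units; the
    transcript-to-enzyme proxy is absorbed into it.  thermo_threshold (τ,
    kJ·mol⁻¹) is the ΔG′° dead band inside which directionality is left
    untouched.  default_uptake backstops medium entries without a rate.
    """

    capacity_scale: float = 1.0
    thermo_threshold: float = 10.0
    default_uptake: float = 10.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.capacity_scale) and self.capacity_scale > 0):
            raise ValueError(f"capacity_scale must be > 0, got {self.capacity_scale}")
        if not (math.isfinite(self.thermo_threshold) and self.thermo_threshold >= 0):
            raise ValueError(f"thermo_threshold must be >= 0, got {self.thermo_threshold}")
        if not math.isfinite(self.default_uptake) or self.default_uptake < 0:
            raise ValueError(f"default_uptake must be >= 0, got {self.default_uptake}")


def aggregate_gpr_abundance(gpr: GPRTree, profile: ExpressionProfile) -> float | None:
    """Reaction-level enzyme abundance from a GPR tree.

    AND = min of children (complex limited by scarcest subunit), OR = sum of
    children (isoenzymes add), missing genes contribute 0, empty tree maps
    to ``None`` (no enzyme information).
    """
    if gpr.kind == "empty":
        return None
    if gpr.kind == "gene":
        return float(profile.values.get(gpr.gene, 0.0))
    child_values = [aggregate_gpr_abundance(c, profile) for c in gpr.children]
    if gpr.kind == "and":
        return min(child_values)  # type: ignore[type-var]
    return sum(child_values)  # type: ignore[arg-type]


def capacity_bounds(
    network: MetabolicNetwork,
    profile: ExpressionProfile,
    config: ConstraintConfig = ConstraintConfig(),
) -> MetabolicNetwork:
    """Tighten bounds to the enzyme capacity σ·kcat·a per reaction.

    Reactions lacking kcat or with an empty GPR are untouched (absent data
    is not a zero bound).  Reversible reactions get the symmetric bound on
    the reverse direction.
    """
    new_reactions = []
    for r in network.reactions:
        a = aggregate_gpr_abundance(r.gpr, profile)
        if r.kcat is None or a is None:
            new_reactions.append(r)
            continue
        cap = config.capacity_scale * r.kcat * a
        ub = min(r.upper_bound, cap)
        lb = max(r.lower_bound, -cap) if r.lower_bound < 0 else r.lower_bound
        new_reactions.append(replace(r, lower_bound=lb, upper_bound=ub))
    return network.with_reactions(new_reactions)


def thermodynamic_directions(
    network: MetabolicNetwork, config: ConstraintConfig = ConstraintConfig()
) -> MetabolicNetwork:
    """Constrain reaction direction by the sign of ΔG′° outside the ±τ band.

    ΔG′° < −τ forces forward-only; ΔG′° > +τ forces reverse-only; values in
    the band, or absent, leave bounds unchanged.  A conflict with existing
    bounds collapses the reaction to [0, 0] with a warning.
    """
    tau = config.thermo_threshold
    new_reactions = []
    for r in network.reactions:
        dg = r.delta_g_prime
        if dg is None or abs(dg) <= tau:
            new_reactions.append(r)
            continue
        if dg < -tau:
            lb, ub = max(r.lower_bound, 0.0), r.upper_bound
        else:
            lb, ub = r.lower_bound, min(r.upper_bound, 0.0)
        if lb > ub:
            warnings.warn(
                f"thermodynamic direction of {r.id} conflicts with its bounds; "
                "collapsing to [0, 0]",
                stacklevel=2,
            )
            lb = ub = 0.0
        new_reactions.append(replace(r, lower_bound=lb, upper_bound=ub))
    return network.with_reactions(new_reactions)


def apply_medium(
    network: MetabolicNetwork,
    medium: MediumTable,
    config: ConstraintConfig = ConstraintConfig(),
) -> MetabolicNetwork:
    """Set exchange lower bounds from the medium composition.

    Metabolites in the medium may be taken up at most at their listed rate
    (exchange lb = −rate); all other uptake is blocked (lb = 0).  Secretion
    (upper bounds) is never touched.  Medium metabolites without an exchange
    reaction trigger a warning listing their ids.
    """
    exchanged: set[str] = set()
    new_reactions = []
    for r in network.reactions:
        if not r.is_exchange:
            new_reactions.append(r)
            continue
        (mid,) = r.stoichiometry.keys()
        exchanged.add(mid)
        if mid in medium.entries:
            rate = medium.entries[mid]
            if rate is None:
                rate = config.default_uptake
            new_reactions.append(replace(r, lower_bound=-rate))
        else:
            new_reactions.append(replace(r, lower_bound=0.0))
    missing = sorted(set(medium.entries) - exchanged)
    if missing:
        warnings.warn(
            f"medium metabolites without exchange reactions: {missing}", stacklevel=2
        )
    return network.with_reactions(new_reactions)


def attach_annotations(
    network: MetabolicNetwork,
    kcat: dict[str, float] | None = None,
    delta_g_prime: dict[str, float] | None = None,
) -> MetabolicNetwork:
    """Copy of the network with kcat / ΔG′° values attached by reaction id."""
    kcat = kcat or {}
    delta_g_prime = delta_g_prime or {}
    unknown = (set(kcat) | set(delta_g_prime)) - set(network.reaction_ids)
    if unknown:
        warnings.warn(f"annotations for unknown reactions ignored: {sorted(unknown)}")
    new_reactions = []
    for r in network.reactions:
        updates = {}
        if r.id in kcat:
            updates["kcat"] = float(kcat[r.id])
        if r.id in delta_g_prime:
            updates["delta_g_prime"] = float(delta_g_prime[r.id])
        new_reactions.append(replace(r, **updates) if updates else r)
    return network.with_reactions(new_reactions)


# ---------------------------------------------------------------------------
# plain-text readers


def read_expression_tsv(path: str | Path, condition: str, replicate: str) -> ExpressionProfile:
    """Read one replicate from a two-column TSV (gene_id, value)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, value")
    return ExpressionProfile(
        condition=condition,
        replicate=replicate,
        values=dict(zip(df["gene_id"].astype(str), df["value"].astype(float))),
    )


def read_expression_matrix(path: str | Path) -> list[ExpressionProfile]:
    """Read a wide matrix: gene_id column + one ``condition:replicate`` column each."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expected a gene_id column")
    genes = df["gene_id"].astype(str)
    profiles = []
    for col in df.columns:
        if col == "gene_id":
            continue
        if ":" not in col:
            raise ValueError(f"{path}: column {col!r} is not condition:replicate")
        condition, _, replicate = col.partition(":")
        profiles.append(
            ExpressionProfile(
                condition=condition,
                replicate=replicate,
                values=dict(zip(genes, df[col].astype(float))),
            )
        )
    return profiles


def write_expression_matrix(profiles: list[ExpressionProfile], path: str | Path) -> None:
    """Write profiles as a wide TSV with condition:replicate headers."""
    genes = sorted({g for p in profiles for g in p.values})
    data = {"gene_id": genes}
    for p in profiles:
        data[f"{p.condition}:{p.replicate}"] = [p.values.get(g, 0.0) for g in genes]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_medium_tsv(path: str | Path) -> MediumTable:
    """Read a medium table: metabolite_id, max_uptake (blank = default)."""
    df = pd.read_csv(path, sep="\t")
    if not {"metabolite_id", "max_uptake"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns metabolite_id, max_uptake")
    entries: dict[str, float | None] = {}
    for _, row in df.iterrows():
        rate = row["max_uptake"]
        entries[str(row["metabolite_id"])] = None if pd.isna(rate) else float(rate)
    return MediumTable(entries=entries)


def read_annotation_tsv(path: str | Path, value_column: str) -> dict[str, float]:
    """Read a per-reaction annotation table (reaction_id + one value column)."""
    df = pd.read_csv(path, sep="\t")
    if not {"reaction_id", value_column} <= set(df.columns):
        raise ValueError(f"{path}: expected columns reaction_id, {value_column}")
    return dict(zip(df["reaction_id"].astype(str), df[value_column].astype(float)))


def read_config(path: str | Path) -> ConstraintConfig:
    """Read a key=value config file (capacity_scale, thermo_threshold, default_uptake)."""
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        key = key.strip()
        if key not in ("capacity_scale", "thermo_threshold", "default_uptake"):
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        kwargs[key] = float(value.strip())
    return ConstraintConfig(**kwargs)
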