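"""Data model and I/O for constraint-based metabolic networks.

The in-memory model mirrors the schema of genome-scale reconstructions such
as Recon3D: metabolites with compartments, reactions with stoichiometry,
flux bounds (mmol·gDW⁻¹·h⁻¹), subsystem labels, GPR rules and optional
enzyme turnover numbers (kcat, s⁻¹) and standard transformed Gibbs free
energies (ΔG′°, kJ·mol⁻¹), plus a designated biomass objective reaction.

Two native on-disk formats are normative — a JSON dialect and a two-file
TSV dialect (``reactions.tsv`` + ``metabolites.tsv``) — both written with
sorted keys so serialization is byte-deterministic.  SBML Level 3 (fbc)
reading is supported as best-effort interop via cobrapy.

Exchange convention: an exchange reaction ``EX_m`` is written ``1 m <-> ∅``
with stoichiometric coefficient −1; negative flux is uptake, positive flux
is secretion.  Medium composition therefore maps to exchange lower bounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .gpr import GPRTree, parse_gpr, render_gpr

__all__ = [
    "MetaboliteRecord",
    "ReactionRecord",
    "MetabolicNetwork",
    "StoichiometricMatrix",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "stoichiometric_matrix",
    "validate_network",
]

DEFAULT_BOUND = 1000.0


class NetworkValidationError(ValueError):
    """Raised when a network violates its structural invariants."""


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class ReactionRecord:
    """A reaction: one column of the stoichiometric matrix S.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed, positive = produced).  ``kcat`` and
    ``delta_g_prime`` are optional annotations; absent means unknown,
    never zero.
    """

    id: str
    name: str = ""
    subsystem: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRTree = field(default_factory=GPRTree.empty)
    kcat: float | None = None
    delta_g_prime: float | None = None
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass(frozen=True)
class MetabolicNetwork:
    metabolites: tuple[MetaboliteRecord, ...]
    reactions: tuple[ReactionRecord, ...]
    objective_id: str
    name: str = "network"

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def genes(self) -> set[str]:
        from .gpr import gpr_genes

        out: set[str] = set()
        for r in self.reactions:
            out |= gpr_genes(r.gpr)
        return out

    def with_reactions(self, reactions: list[ReactionRecord]) -> "MetabolicNetwork":
        """Copy of the network with a replaced reaction list."""
        return replace(self, reactions=tuple(reactions))


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Sparse S with ordered row (metabolite) and column (reaction) ids."""

    S: sp.csr_matrix
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]


def validate_network(network: MetabolicNetwork) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    violations: list[str] = []
    met_ids = [m.id for m in network.metabolites]
    met_set = set(met_ids)
    if len(met_set) != len(met_ids):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        violations.append(f"duplicate metabolite ids: {dupes}")
    for m in network.metabolites:
        if not m.compartment:
            violations.append(f"metabolite {m.id}: empty compartment")
    rxn_ids = [r.id for r in network.reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        violations.append(f"duplicate reaction ids: {dupes}")
    for r in network.reactions:
        if r.lower_bound > r.upper_bound:
            violations.append(
                f"reaction {r.id}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
            )
        if not r.stoichiometry:
            violations.append(f"reaction {r.id}: empty stoichiometry")
        if r.is_exchange and len(r.stoichiometry) != 1:
            violations.append(
                f"reaction {r.id}: exchange must involve exactly one metabolite"
            )
        for mid in r.stoichiometry:
            if mid not in met_set:
                violations.append(f"reaction {r.id}: unknown metabolite {mid!r}")
        for val in (r.lower_bound, r.upper_bound, r.kcat, r.delta_g_prime):
            if val is not None and not math.isfinite(val):
                violations.append(f"reaction {r.id}: non-finite numeric field")
                break
    if network.objective_id not in set(rxn_ids):
        violations.append(f"objective reaction {network.objective_id!r} not in network")
    return violations


def _require_valid(network: MetabolicNetwork) -> None:
    violations = validate_network(network)
    if violations:
        raise NetworkValidationError("; ".join(violations))


def stoichiometric_matrix(network: MetabolicNetwork) -> StoichiometricMatrix:
    """Assemble sparse S (metabolites × reactions) in input order."""
    _require_valid(network)
    met_index = {m.id: i for i, m in enumerate(network.metabolites)}
    rows, cols, data = [], [], []
    for j, r in enumerate(network.reactions):
        for mid, coef in r.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coef))
    S = sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(network.metabolites), len(network.reactions)),
    )
    return StoichiometricMatrix(
        S=S,
        row_ids=tuple(network.metabolite_ids),
        col_ids=tuple(network.reaction_ids),
    )


# ---------------------------------------------------------------------------
# serialization


def _fmt(x: float) -> str:
    return repr(float(x))


def _reaction_to_dict(r: ReactionRecord) -> dict:
    d: dict = {
        "id": r.id,
        "name": r.name,
        "subsystem": r.subsystem,
        "stoichiometry": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
        "lower_bound": float(r.lower_bound),
        "upper_bound": float(r.upper_bound),
        "gpr": render_gpr(r.gpr),
        "is_exchange": bool(r.is_exchange),
    }
    if r.kcat is not None:
        d["kcat"] = float(r.kcat)
    if r.delta_g_prime is not None:
        d["delta_g_prime"] = float(r.delta_g_prime)
    return d


def _reaction_from_dict(d: dict, context: str) -> ReactionRecord:
    try:
        return ReactionRecord(
            id=d["id"],
            name=d.get("name", ""),
            subsystem=d.get("subsystem", ""),
            stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
            lower_bound=float(d["lower_bound"]),
            upper_bound=float(d["upper_bound"]),
            gpr=parse_gpr(d.get("gpr", "")),
            kcat=None if d.get("kcat") is None else float(d["kcat"]),
            delta_g_prime=(
                None if d.get("delta_g_prime") is None else float(d["delta_g_prime"])
            ),
            is_exchange=bool(d.get("is_exchange", False)),
        )
    except KeyError as exc:
        raise NetworkValidationError(f"{context}: missing field {exc}") from exc


def _to_json_obj(network: MetabolicNetwork) -> dict:
    return {
        "name": network.name,
        "objective_id": network.objective_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in network.metabolites
        ],
        "reactions": [_reaction_to_dict(r) for r in network.reactions],
    }


def _from_json_obj(obj: dict, context: str) -> MetabolicNetwork:
    try:
        mets = tuple(
            MetaboliteRecord(
                id=m["id"], name=m.get("name", ""), compartment=m["compartment"]
            )
            for m in obj["metabolites"]
        )
        rxns = tuple(
            _reaction_from_dict(r, f"{context}: reaction {r.get('id', '?')}")
            for r in obj["reactions"]
        )
        net = MetabolicNetwork(
            metabolites=mets,
            reactions=rxns,
            objective_id=obj["objective_id"],
            name=obj.get("name", "network"),
        )
    except (KeyError, TypeError) as exc:
        raise NetworkValidationError(f"{context}: malformed network object ({exc})") from exc
    _require_valid(net)
    return net


_TSV_REACTION_COLS = [
    "id",
    "name",
    "subsystem",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "gpr",
    "kcat",
    "delta_g_prime",
    "is_exchange",
]


def _encode_stoich(stoich: dict[str, float]) -> str:
    return ";".join(f"{mid}:{_fmt(coef)}" for mid, coef in sorted(stoich.items()))


def _decode_stoich(text: str, context: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not text:
        return out
    for part in text.split(";"):
        mid, _, coef = part.rpartition(":")
        if not mid:
            raise NetworkValidationError(f"{context}: malformed stoichiometry term {part!r}")
        out[mid] = float(coef)
    return out


def _write_tsv(network: MetabolicNetwork, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    met_lines = ["id\tname\tcompartment"]
    met_lines += [f"{m.id}\t{m.name}\t{m.compartment}" for m in network.metabolites]
    (directory / "metabolites.tsv").write_text("\n".join(met_lines) + "\n")
    rxn_lines = ["\t".join(_TSV_REACTION_COLS + ["objective"])]
    for r in network.reactions:
        row = [
            r.id,
            r.name,
            r.subsystem,
            _encode_stoich(r.stoichiometry),
            _fmt(r.lower_bound),
            _fmt(r.upper_bound),
            render_gpr(r.gpr),
            "" if r.kcat is None else _fmt(r.kcat),
            "" if r.delta_g_prime is None else _fmt(r.delta_g_prime),
            "1" if r.is_exchange else "0",
            "1" if r.id == network.objective_id else "0",
        ]
        rxn_lines.append("\t".join(row))
    (directory / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n")


def _read_tsv(directory: Path) -> MetabolicNetwork:
    met_path = directory / "metabolites.tsv"
    rxn_path = directory / "reactions.tsv"
    for p in (met_path, rxn_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mets = []
    lines = met_path.read_text().rstrip("\n").split("\n")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 3:
            raise NetworkValidationError(f"{met_path}:{lineno}: expected 3 columns")
        mets.append(MetaboliteRecord(id=parts[0], name=parts[1], compartment=parts[2]))
    rxns = []
    objective_id = None
    lines = rxn_path.read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if header != _TSV_REACTION_COLS + ["objective"]:
        raise NetworkValidationError(f"{rxn_path}:1: unexpected header {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise NetworkValidationError(f"{rxn_path}:{lineno}: wrong column count")
        row = dict(zip(header, parts))
        rxn = ReactionRecord(
            id=row["id"],
            name=row["name"],
            subsystem=row["subsystem"],
            stoichiometry=_decode_stoich(row["stoichiometry"], f"{rxn_path}:{lineno}"),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            gpr=parse_gpr(row["gpr"]),
            kcat=float(row["kcat"]) if row["kcat"] else None,
            delta_g_prime=float(row["delta_g_prime"]) if row["delta_g_prime"] else None,
            is_exchange=row["is_exchange"] == "1",
        )
        rxns.append(rxn)
        if row["objective"] == "1":
            objective_id = rxn.id
    if objective_id is None:
        raise NetworkValidationError(f"{rxn_path}: no reaction flagged as objective")
    net = MetabolicNetwork(
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        objective_id=objective_id,
        name=directory.name,
    )
    _require_valid(net)
    return net


def _read_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML reading requires the 'cobra' package") from exc
    model = cobra.io.read_sbml_model(str(path))
    mets = tuple(
        MetaboliteRecord(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in model.metabolites
    )
    objective_ids = [
        r.id for r in model.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    rxns = []
    for r in model.reactions:
        rxns.append(
            ReactionRecord(
                id=r.id,
                name=r.name or "",
                subsystem=r.subsystem or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule or ""),
                is_exchange=len(r.metabolites) == 1,
            )
        )
    if not objective_ids:
        raise NetworkValidationError(f"{path}: SBML model declares no objective")
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=tuple(rxns),
        objective_id=objective_ids[0],
        name=model.id or path.stem,
    )
    _require_valid(net)
    return net


def read_network(path: str | Path, format: str = "native-json") -> MetabolicNetwork:
    """Read a network from disk.

    ``format`` is one of ``native-json``, ``native-tsv`` (path is the
    directory holding ``reactions.tsv``/``metabolites.tsv``) or ``sbml``.
    Optional annotations absent from the file stay absent (``None``).
    """
    path = Path(path)
    if format == "native-json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkValidationError(f"{path}:{exc.lineno}: JSON parse error: {exc.msg}")
        return _from_json_obj(obj, str(path))
    if format == "native-tsv":
        return _read_tsv(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(
    network: MetabolicNetwork, path: str | Path, format: str = "native-json"
) -> None:
    """Write a network; output re-reads to an equal network and is
    byte-deterministic (map keys sorted)."""
    _require_valid(network)
    path = Path(path)
    if format == "native-json":
        text = json.dumps(_to_json_obj(network), sort_keys=True, indent=1)
        path.write_text(text + "\n")
    elif format == "native-tsv":
        _write_tsv(network, path)
    else:
        raise ValueError(f"unsupported write format {format!r}")
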