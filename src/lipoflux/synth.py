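"""Synthetic inputs with planted ground truth for every pipeline stage.

All generators are pure functions of their parameters and seed
(``numpy.random.default_rng``), so the same call is reproducible
bit-for-bit across platforms.  Each generator also returns (or can write)
its ground truth so tests never re-derive planted effects.

* :func:`make_toy_network` — a small metabolic network shaped like a
  genome-scale reconstruction: one exchange + linear conversion chain per
  subsystem, every internal reaction gene-annotated with a sampled kcat,
  a configurable fraction carrying ΔG′°, all chains feeding a biomass
  objective.  Feasible with positive biomass under the default medium.
* :func:`make_expression_replicates` — lognormal multiplicative expression
  noise around a common baseline, with a planted fold change on a chosen
  gene set or subsystem in the treated condition (default 3 replicates per
  condition, matching a typical bulk RNA-seq design).
* :func:`make_genomic_fixture` — genes tiled on a synthetic chromosome
  with planted class-conditional DAR placement (promoter / gene body /
  downstream) plus distal filler; DAR direction drawn from a configurable
  up-fraction (default 0.84, the skew typical of accessibility gains
  dominating losses).
* :func:`make_cell_image` — concentric two-channel cell images with a
  planted perinuclear enrichment ratio and optional lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import DARRecord, GeneModel, REGIONS
from .constraints import ExpressionProfile, MediumTable
from .gpr import GPRTree
from .network import MetabolicNetwork, MetaboliteRecord, ReactionRecord
from .pnpr import CellImage, CellMasks, normalized_distance

__all__ = [
    "ToyNetworkSpec",
    "PlantedEffect",
    "GenomicPlant",
    "make_toy_network",
    "default_medium",
    "make_expression_replicates",
    "make_genomic_fixture",
    "make_cell_image",
]


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Shape of a generated toy network."""

    n_subsystems: int = 4
    reactions_per_subsystem: int = 4
    include_biomass: bool = True
    kcat_range: tuple[float, float] = (1.0, 5.0)
    dgp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsystems < 1 or self.reactions_per_subsystem < 1:
            raise ValueError("n_subsystems and reactions_per_subsystem must be >= 1")
        if not 0 <= self.dgp_fraction <= 1:
            raise ValueError("dgp_fraction must be in [0, 1]")
        lo, hi = self.kcat_range
        if not 0 < lo <= hi:
            raise ValueError("kcat_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class PlantedEffect:
    """A planted condition effect on expression.

    ``target`` is a subsystem id (its reactions' genes) or an explicit
    tuple of gene ids; ``effect_size`` multiplies target-gene abundance in
    the treated condition; replicate abundances carry multiplicative
    lognormal noise of log-sd ``noise_sd``.
    """

    target: str | tuple[str, ...]
    effect_size: float = 4.0
    noise_sd: float = 0.2
    n_replicates: int = 3
    seed: int = 0
    condition_labels: tuple[str, str] = ("UCM", "ACM")

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GenomicPlant:
    """Class-conditional DAR planting probabilities.

    ``dar_probs`` maps (gene_class, region) to the probability that each
    gene of that class receives one DAR in that region; unlisted cells use
    ``default_prob``.  ``dar_up_fraction`` is the probability a planted or
    distal DAR has increased accessibility.
    """

    up_fraction: float = 0.25
    down_fraction: float = 0.15
    dar_up_fraction: float = 0.84
    default_prob: float = 0.3
    dar_probs: dict = field(default_factory=dict)

    def prob(self, gene_class: str, region: str) -> float:
        return float(self.dar_probs.get((gene_class, region), self.default_prob))


def make_toy_network(spec: ToyNetworkSpec) -> MetabolicNetwork:
    """Generate a feasible toy network per the spec (seed-deterministic).

    Each subsystem is an uptake chain ``EX -> m0 -> m1 -> ... -> bm``; the
    final product of every chain is the shared biomass precursor, consumed
    by the biomass objective, so each chain contributes additively to
    growth and responds independently to its own enzymes' capacities.
    """
    rng = np.random.default_rng(spec.seed)
    mets: list[MetaboliteRecord] = []
    rxns: list[ReactionRecord] = []
    k = spec.reactions_per_subsystem
    lo, hi = spec.kcat_range
    internal_ids: list[str] = []
    for s in range(1, spec.n_subsystems + 1):
        sub = f"subsystem_{s}"
        chain_mets = [f"m{s}_{j}" for j in range(k)]
        for j, mid in enumerate(chain_mets):
            mets.append(
                MetaboliteRecord(
                    id=mid, name=f"metabolite {s}.{j}",
                    compartment="e" if j == 0 else "c",
                )
            )
        rxns.append(
            ReactionRecord(
                id=f"EX_m{s}_0",
                name=f"exchange of m{s}_0",
                subsystem="Exchange",
                stoichiometry={chain_mets[0]: -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
                is_exchange=True,
            )
        )
        targets = chain_mets[1:] + ["bm" if spec.include_biomass else f"t{s}"]
        for j in range(k):
            rid = f"R{s}_{j + 1}"
            internal_ids.append(rid)
            rxns.append(
                ReactionRecord(
                    id=rid,
                    name=f"conversion {s}.{j + 1}",
                    subsystem=sub,
                    stoichiometry={chain_mets[j]: -1.0, targets[j]: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    gpr=GPRTree.gene_node(f"G{s}_{j + 1}"),
                    kcat=float(rng.uniform(lo, hi)),
                )
            )
        if not spec.include_biomass:
            mets.append(MetaboliteRecord(id=f"t{s}", name=f"terminal {s}", compartment="c"))
            rxns.append(
                ReactionRecord(
                    id=f"EX_t{s}",
                    name=f"secretion of t{s}",
                    subsystem="Exchange",
                    stoichiometry={f"t{s}": -1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    is_exchange=True,
                )
            )
    if spec.include_biomass:
        mets.append(MetaboliteRecord(id="bm", name="biomass precursor", compartment="c"))
        rxns.append(
            ReactionRecord(
                id="biomass",
                name="biomass objective",
                subsystem="Biomass",
                stoichiometry={"bm": -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
        objective_id = "biomass"
    else:
        objective_id = "EX_t1"
    # ΔG′° on a sampled fraction of internal reactions, forward-favoring
    n_dgp = int(round(spec.dgp_fraction * len(internal_ids)))
    chosen = set(rng.choice(internal_ids, size=n_dgp, replace=False)) if n_dgp else set()
    dgp_values = {rid: float(rng.uniform(-40.0, -15.0)) for rid in sorted(chosen)}
    from dataclasses import replace as _replace

    rxns = [
        r if r.id not in dgp_values else _replace(r, delta_g_prime=dgp_values[r.id])
        for r in rxns
    ]
    return MetabolicNetwork(
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        objective_id=objective_id,
        name=f"toy_{spec.n_subsystems}x{k}_seed{spec.seed}",
    )


def default_medium(network: MetabolicNetwork, uptake: float = 100.0) -> MediumTable:
    """Medium allowing uptake of every exchanged metabolite at a flat rate.

    The default rate is deliberately generous so that enzyme-capacity
    constraints, not uptake, limit flux in generated models.
    """
    entries = {}
    for r in network.reactions:
        if r.is_exchange:
            (mid,) = r.stoichiometry.keys()
            entries[mid] = uptake
    return MediumTable(entries=entries)


def _target_genes(network: MetabolicNetwork, target) -> list[str]:
    if isinstance(target, str):
        genes = sorted(
            g
            for r in network.reactions
            if r.subsystem == target
            for g in _gpr_gene_list(r.gpr)
        )
        if not genes:
            raise ValueError(f"subsystem {target!r} has no genes in the network")
        return genes
    genes = sorted(set(target))
    unknown = set(genes) - network.genes()
    if unknown:
        raise ValueError(f"target genes not in network: {sorted(unknown)}")
    return genes


def _gpr_gene_list(gpr: GPRTree) -> list[str]:
    from .gpr import gpr_genes

    return sorted(gpr_genes(gpr))


def make_expression_replicates(
    network: MetabolicNetwork, effect: PlantedEffect
) -> list[ExpressionProfile]:
    """Expression replicates for both conditions with the planted effect.

    Every gene's abundance is 1.0 × lognormal(0, noise_sd) per replicate;
    treated-condition target genes are multiplied by ``effect_size``.
    Profiles are ordered condition-major (control first).
    """
    genes = sorted(network.genes())
    targets = set(_target_genes(network, effect.target))
    rng = np.random.default_rng(effect.seed)
    profiles = []
    ctrl_label, treat_label = effect.condition_labels
    for condition in (ctrl_label, treat_label):
        for rep in range(1, effect.n_replicates + 1):
            noise = rng.lognormal(mean=0.0, sigma=effect.noise_sd, size=len(genes))
            values = {}
            for g, z in zip(genes, noise):
                a = float(z)
                if condition == treat_label and g in targets:
                    a *= effect.effect_size
                values[g] = a
            profiles.append(
                ExpressionProfile(condition=condition, replicate=f"R{rep}", values=values)
            )
    return profiles


def make_genomic_fixture(
    n_genes: int,
    n_dars: int,
    planted: GenomicPlant = GenomicPlant(),
    seed: int = 0,
    chrom: str = "chrS",
    chrom_length: int | None = None,
) -> tuple[list[GeneModel], list[DARRecord], pd.DataFrame, dict]:
    """Genes, DARs and a DE table on a synthetic chromosome.

    Genes are tiled with >= 9 kb spacing so the 3 kb promoter/downstream
    windows of neighboring genes never collide; planted DARs therefore
    have an unambiguous ground-truth (gene, region) assignment.  Distal
    DARs fill the remaining requested count and sit >= 3 kb from every
    gene.  Returns ``(genes, dars, de_table, truth)``.
    """
    if n_genes < 1 or n_dars < 0:
        raise ValueError("n_genes must be >= 1 and n_dars >= 0")
    rng = np.random.default_rng(seed)

    # class assignment to hit requested proportions
    n_up = int(round(planted.up_fraction * n_genes))
    n_down = int(round(planted.down_fraction * n_genes))
    if n_up + n_down > n_genes:
        raise ValueError("class fractions exceed 1")
    classes = np.array(
        ["Up"] * n_up + ["Down"] * n_down + ["Unchanged"] * (n_genes - n_up - n_down)
    )
    rng.shuffle(classes)

    genes: list[GeneModel] = []
    pos = 0
    for i in range(n_genes):
        gap = int(rng.integers(9000, 15000))
        start = pos + gap
        length = int(rng.integers(2000, 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene_{i:05d}", chrom=chrom, start=start, end=start + length,
                strand=strand,
            )
        )
        pos = start + length
    if chrom_length is not None and pos + 9000 > chrom_length:
        raise ValueError(
            f"overcrowded chromosome: layout needs {pos + 9000} bp > {chrom_length}"
        )

    # DE table consistent with the planted classes (thresholds 0.58 / 0.05)
    de_rows = []
    for g, cls in zip(genes, classes):
        if cls == "Up":
            lfc, p = rng.uniform(0.58, 3.0), rng.uniform(0.0, 0.05)
        elif cls == "Down":
            lfc, p = -rng.uniform(0.58, 3.0), rng.uniform(0.0, 0.05)
        else:
            lfc, p = rng.uniform(-0.57, 0.57), rng.uniform(0.0, 1.0)
        de_rows.append((g.gene_id, float(lfc), float(p)))
    de_table = pd.DataFrame(de_rows, columns=["gene_id", "log2FC", "p"])

    def _draw_dar(window: tuple[int, int]) -> tuple[int, int, str]:
        lo, hi = window
        width = min(200, hi - lo)
        start = int(rng.integers(lo, hi - width + 1)) if hi - width > lo else lo
        direction = "Up" if rng.random() < planted.dar_up_fraction else "Down"
        return start, start + width, direction

    dars: list[DARRecord] = []
    planted_truth = []
    for g, cls in zip(genes, classes):
        for region in REGIONS:
            if rng.random() >= planted.prob(cls, region):
                continue
            start, end, direction = _draw_dar(g.region_window(region))
            lfc = rng.uniform(0.1, 1.0) * (1 if direction == "Up" else -1)
            dars.append(
                DARRecord(chrom=chrom, start=start, end=end, log2fc=float(lfc),
                          fdr=float(rng.uniform(0.0, 0.05)))
            )
            planted_truth.append(
                {"gene_id": g.gene_id, "region": region, "direction": direction}
            )
    # distal filler, >= 3 kb clear of every gene
    n_distal = max(0, n_dars - len(dars))
    for _ in range(n_distal):
        gi = int(rng.integers(0, n_genes))
        left = genes[gi - 1].end if gi > 0 else 0
        lo, hi = left + 3001, genes[gi].start - 3001 - 200
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        direction = "Up" if rng.random() < planted.dar_up_fraction else "Down"
        lfc = rng.uniform(0.1, 1.0) * (1 if direction == "Up" else -1)
        dars.append(
            DARRecord(chrom=chrom, start=start, end=start + 200, log2fc=float(lfc),
                      fdr=float(rng.uniform(0.0, 0.05)))
        )
    truth = {
        "classes": {g.gene_id: str(c) for g, c in zip(genes, classes)},
        "planted_dars": planted_truth,
        "n_distal": n_distal,
    }
    return genes, dars, de_table, truth


def make_cell_image(
    shape: tuple[int, int] = (96, 96),
    nucleus_radius: float = 12.0,
    cell_radius: float = 36.0,
    perinuclear_ratio: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_intensity: float = 100.0,
    dna_intensity: float = 200.0,
    band: float = 0.25,
) -> tuple[CellImage, CellMasks]:
    """Concentric synthetic cell with planted perinuclear enrichment.

    The DNA channel is a disk nucleus; the signal channel covers the whole
    cell at ``base_intensity``, multiplied by ``perinuclear_ratio`` in the
    inner ``band`` fraction of normalized cytoplasmic distance (the same
    distance definition the profiling uses, so on the ground-truth masks a
    noiseless image yields PNPR exactly equal to the planted ratio).
    Optional multiplicative lognormal noise.  Returns the image and its
    ground-truth masks.
    """
    if perinuclear_ratio <= 0:
        raise ValueError("perinuclear_ratio must be > 0")
    if not 0 < nucleus_radius < cell_radius:
        raise ValueError("need 0 < nucleus_radius < cell_radius")
    if cell_radius >= min(shape) / 2:
        raise ValueError("cell_radius exceeds the image half-size")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
    nucleus = r <= nucleus_radius
    cell = r <= cell_radius
    masks = CellMasks(nucleus_mask=nucleus, cell_mask=cell)
    d = normalized_distance(masks)
    signal = np.zeros(shape, dtype=float)
    signal[cell] = base_intensity
    inner = masks.cytoplasm_mask & (d < band)
    signal[inner] *= perinuclear_ratio
    dna = np.where(nucleus, dna_intensity, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal * rng.lognormal(0.0, noise_sd, size=shape)
        dna = dna * rng.lognormal(0.0, noise_sd, size=shape)
    return CellImage(signal_channel=signal, dna_channel=dna), masks
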