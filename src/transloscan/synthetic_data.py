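"""Synthetic genomes, qPCR tables and drop tests with planted ground truth.

The generator emulates the study design the pipeline targets: multi-
chromosome genomes of uniformly spaced orthologous genes, a reciprocal
translocation planted a configurable distance upstream of a focal gene with
a k-bp microhomology tract at the junction, K81-model sequence divergence
between strains, an identical-by-state gene block copied between two
strains, qPCR Ct tables with Gaussian cycle noise and a dilution series,
and ordinal drop-test growth scores on a sulfite concentration grid.
Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression_quant import PERFECT_SLOPE, QpcrDataset
from .genome_io import (
    AnnotatedGenome,
    GeneFeature,
    OrthologMap,
    gene_start,
    reverse_complement,
    write_annotated_genome,
    write_ortholog_table,
)
from .phenotype_tolerance import DEFAULT_GRID, DropTestTable, _conc_col

__all__ = [
    "SimulationConfig",
    "TranslocationSpec",
    "QpcrSpec",
    "DropTestSpec",
    "ScenarioConfig",
    "Scenario",
    "simulate_reference",
    "build_ortholog_map",
    "apply_translocation",
    "plant_microhomology",
    "evolve_k81",
    "plant_shared_block",
    "simulate_qpcr",
    "simulate_droptest",
    "simulate_scenario",
    "write_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# partner maps by base code for the three K81 substitution classes
_TS = np.array([2, 3, 0, 1], dtype=np.uint8)
_TV1 = np.array([3, 2, 1, 0], dtype=np.uint8)
_TV2 = np.array([1, 0, 3, 2], dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Layout of the ancestral reference genome.

    Genes are uniformly spaced: gene i on a chromosome starts at
    intergenic + i*(gene_length+intergenic) + 1 (1-based). The focal gene is
    addressed by (focal_chromosome, focal_index); a transcription-factor
    motif is planted at ``motif_distance`` bp upstream of its start (offset
    of the motif's most distal base) after scrubbing chance occurrences from
    the promoter window.
    """

    seed: int
    n_chromosomes: int = 3
    genes_per_chromosome: int = 70
    gene_length: int = 1000
    intergenic_length: int = 600
    focal_chromosome: str = "chr3"
    focal_index: int = 36
    alternate_strands: bool = False
    motif: str = "CTATCA"
    motif_distance: int = 500
    motif_window: int = 5000

    def __post_init__(self) -> None:
        if self.genes_per_chromosome < 1 or self.n_chromosomes < 1:
            raise ConfigError("need at least one gene on one chromosome")
        if self.motif_distance >= self.intergenic_length:
            raise ConfigError("motif must land in the focal intergenic region")

    @property
    def focal_ortholog(self) -> str:
        chrom_i = int(self.focal_chromosome.removeprefix("chr")) - 1
        return _og_id(chrom_i * self.genes_per_chromosome + self.focal_index)


def _og_id(i: int) -> str:
    return f"OG{i:04d}"


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_reference(config: SimulationConfig) -> tuple[AnnotatedGenome, OrthologMap]:
    """Ancestral reference genome plus its ortholog table.

    Deterministic given config.seed; every gene receives an ortholog label.
    """
    rng = np.random.default_rng(config.seed)
    pitch = config.gene_length + config.intergenic_length
    chrom_len = config.genes_per_chromosome * pitch + config.intergenic_length
    chromosomes: dict[str, str] = {}
    genes: list[GeneFeature] = []
    og = 0
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        chromosomes[name] = _rand_seq(rng, chrom_len)
        for i in range(config.genes_per_chromosome):
            start = config.intergenic_length + i * pitch + 1
            strand = "-" if (config.alternate_strands and i % 2) else "+"
            ortholog = _og_id(og)
            genes.append(
                GeneFeature(
                    gene_id=f"REF_{ortholog}",
                    chromosome=name,
                    start=start,
                    end=start + config.gene_length - 1,
                    strand=strand,
                    ortholog_id=ortholog,
                )
            )
            og += 1
    genome = AnnotatedGenome(strain_id="REF", chromosomes=chromosomes, genes=genes)
    _plant_motif(genome, config, rng)
    return genome, build_ortholog_map([genome])


def _plant_motif(
    genome: AnnotatedGenome, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Scrub chance motif hits from the focal promoter window, then write
    one copy with its most distal base ``motif_distance`` bp upstream."""
    focal = genome.find_ortholog(config.focal_ortholog)
    if focal is None or focal.strand != "+":
        raise ConfigError("focal gene must exist on the + strand")
    chrom = bytearray(genome.chromosomes[focal.chromosome].encode())
    fs = focal.start - 1  # 0-based index of the gene's first base
    lo = max(0, fs - config.motif_window)
    motifs = {config.motif.encode(), reverse_complement(config.motif).encode()}
    changed = True
    while changed:
        changed = False
        window = bytes(chrom[lo:fs])
        for m in motifs:
            j = window.find(m)
            if j >= 0:
                mid = lo + j + len(m) // 2
                cur = chrom[mid]
                for repl in b"ACGT":
                    if repl != cur:
                        chrom[mid] = repl
                        break
                changed = True
    p = config.motif_distance
    start = fs - p  # motif occupies offsets p .. p-len+1 upstream
    chrom[start : start + len(config.motif)] = config.motif.encode()
    genome.chromosomes[focal.chromosome] = chrom.decode()


def build_ortholog_map(genomes: list[AnnotatedGenome]) -> OrthologMap:
    omap = OrthologMap()
    for genome in genomes:
        for g in genome.genes:
            if g.ortholog_id:
                omap.add(g.ortholog_id, genome.strain_id, g.gene_id)
    return omap


# -- reciprocal translocation ---------------------------------------------


@dataclass(frozen=True)
class TranslocationSpec:
    """Reciprocal translocation upstream of the focal gene.

    ``offset``: junction distance in bp upstream of the focal gene start.
    ``microhomology``: length of the identical tract planted immediately 5'
    of both parental breakpoints. ``partner_breakpoint`` (1-based, first
    base that stays distal of the partner junction) defaults to the middle
    intergenic gap of the partner chromosome.
    """

    partner_chromosome: str
    offset: int = 339
    microhomology: int = 8
    partner_breakpoint: int | None = None
    seed: int = 0


def _in_gene(genome: AnnotatedGenome, chrom: str, idx0: int) -> GeneFeature | None:
    """Gene containing 0-based position idx0, if any."""
    for g in genome.genes_on(chrom):
        if g.start - 1 <= idx0 < g.end:
            return g
    return None


def _breakpoints(
    genome: AnnotatedGenome, focal: str, spec: TranslocationSpec
) -> tuple[GeneFeature, int, int]:
    """0-based breakpoint indices on the focal and partner chromosomes."""
    focal_gene = genome.find_ortholog(focal)
    if focal_gene is None:
        raise ConfigError(f"focal ortholog {focal} absent")
    if focal_gene.strand != "+":
        raise ConfigError("translocation planting requires a + strand focal gene")
    if spec.partner_chromosome not in genome.chromosomes:
        raise ConfigError(
            f"chromosome {spec.partner_chromosome!r} missing "
            "(translocation already applied?)"
        )
    if spec.partner_chromosome == focal_gene.chromosome:
        raise ConfigError("partner must be a different chromosome")
    bp_a = focal_gene.start - 1 - spec.offset
    if bp_a < spec.microhomology + 1:
        raise ConfigError("offset exceeds sequence upstream of the focal gene")
    if spec.partner_breakpoint is not None:
        bp_b = spec.partner_breakpoint - 1
    else:
        on_b = genome.genes_on(spec.partner_chromosome)
        m = len(on_b) // 2
        bp_b = (on_b[m - 1].end + on_b[m].start - 1) // 2
    for chrom, bp in ((focal_gene.chromosome, bp_a), (spec.partner_chromosome, bp_b)):
        for pos in (bp, bp - spec.microhomology - 1):
            hit = _in_gene(genome, chrom, pos)
            if hit is not None:
                raise ConfigError(
                    f"breakpoint/microhomology at {chrom}:{pos + 1} falls "
                    f"inside gene {hit.gene_id}"
                )
    return focal_gene, bp_a, bp_b


def plant_microhomology(
    genome: AnnotatedGenome, focal: str, spec: TranslocationSpec
) -> tuple[AnnotatedGenome, str]:
    """Write an identical k-bp tract immediately 5' of both parental
    breakpoints, and force the bases flanking the tract to differ between
    the parents so junction ambiguity is exactly k bp.

    Idempotent for a fixed spec (the tract is a pure function of spec.seed),
    so it can be applied to the reference genome and re-applied inside
    :func:`apply_translocation` without drift. Returns the modified genome
    and the tract sequence.
    """
    focal_gene, bp_a, bp_b = _breakpoints(genome, focal, spec)
    chrom_a, chrom_b = focal_gene.chromosome, spec.partner_chromosome
    seq_a = bytearray(genome.chromosomes[chrom_a].encode())
    seq_b = bytearray(genome.chromosomes[chrom_b].encode())
    k = spec.microhomology
    rng = np.random.default_rng(spec.seed)
    tract = _rand_seq(rng, k).encode()
    seq_a[bp_a - k : bp_a] = tract
    seq_b[bp_b - k : bp_b] = tract
    # transition partner guarantees a difference without extra randomness
    transition = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T
    for ia, ib in ((bp_a, bp_b), (bp_a - k - 1, bp_b - k - 1)):
        if seq_b[ib] == seq_a[ia]:
            seq_b[ib] = transition.get(seq_a[ia], 65)
    out = genome.copy()
    out.chromosomes[chrom_a] = seq_a.decode()
    out.chromosomes[chrom_b] = seq_b.decode()
    return out, tract.decode()


def apply_translocation(
    genome: AnnotatedGenome,
    focal: str,
    spec: TranslocationSpec,
    strain_id: str | None = None,
) -> tuple[AnnotatedGenome, dict]:
    """Swap the segments distal of the two breakpoints reciprocally.

    The k-bp microhomology tract is first planted immediately 5' of both
    parental breakpoints (see :func:`plant_microhomology`; idempotent, so a
    genome whose reference copy already carries the tract is unchanged),
    then chromosome prefixes are exchanged and gene annotations remapped.
    Total base count is conserved. Returns the derived genome plus a truth
    entry (offset, microhomology, derived chromosome names).
    """
    genome, tract_seq = plant_microhomology(genome, focal, spec)
    focal_gene, bp_a, bp_b = _breakpoints(genome, focal, spec)
    chrom_a, chrom_b = focal_gene.chromosome, spec.partner_chromosome
    seq_a = genome.chromosomes[chrom_a]
    seq_b = genome.chromosomes[chrom_b]
    k = spec.microhomology
    tract = tract_seq.encode()

    der_focal = f"{chrom_b}^{chrom_a}"  # carries the focal gene
    der_other = f"{chrom_a}^{chrom_b}"
    new_chroms = {
        n: s for n, s in genome.chromosomes.items() if n not in (chrom_a, chrom_b)
    }
    new_chroms[der_focal] = seq_b[:bp_b] + seq_a[bp_a:]
    new_chroms[der_other] = seq_a[:bp_a] + seq_b[bp_b:]

    new_genes: list[GeneFeature] = []
    for g in genome.genes:
        if g.chromosome == chrom_a:
            if g.start - 1 >= bp_a:
                shift = bp_b - bp_a
                g = replace(
                    g, chromosome=der_focal, start=g.start + shift, end=g.end + shift
                )
            elif g.end - 1 < bp_a:
                g = replace(g, chromosome=der_other)
            else:
                raise ConfigError(f"gene {g.gene_id} spans the breakpoint")
        elif g.chromosome == chrom_b:
            if g.end - 1 < bp_b:
                g = replace(g, chromosome=der_focal)
            elif g.start - 1 >= bp_b:
                shift = bp_a - bp_b
                g = replace(
                    g, chromosome=der_other, start=g.start + shift, end=g.end + shift
                )
            else:
                raise ConfigError(f"gene {g.gene_id} spans the breakpoint")
        new_genes.append(g)
    derived = AnnotatedGenome(
        strain_id=strain_id or genome.strain_id,
        chromosomes=new_chroms,
        genes=new_genes,
    )
    truth = {
        "variant_class": "translocated",
        "partner_chromosome": chrom_b,
        "offset": spec.offset,
        "microhomology_len": k,
        "microhomology_seq": tract.decode(),
        "derived_focal_chromosome": der_focal,
        "derived_other_chromosome": der_other,
    }
    return derived, truth


# -- K81 evolution ---------------------------------------------------------


def k81_change_probs(
    branch_length: float, fractions: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Per-site probabilities of a net change of each K81 class after a
    branch of the given expected substitutions/site.

    With class-specific rates a, b, c (summing to the branch length):
        P(transition)      = (1 − e1 + e2 − e3) / 4
        P(A<->T / G<->C)   = (1 + e1 − e2 − e3) / 4
        P(A<->C / G<->T)   = (1 − e1 − e2 + e3) / 4
    where e1 = e^{−2(a+c)}, e2 = e^{−2(b+c)}, e3 = e^{−2(a+b)}.
    """
    if branch_length < 0:
        raise ConfigError("branch length must be >= 0")
    if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ConfigError("rate fractions must be nonnegative and sum to 1")
    a, b, c = (branch_length * f for f in fractions)
    e1 = math.exp(-2 * (a + c))
    e2 = math.exp(-2 * (b + c))
    e3 = math.exp(-2 * (a + b))
    return (
        (1 - e1 + e2 - e3) / 4,
        (1 + e1 - e2 - e3) / 4,
        (1 - e1 - e2 + e3) / 4,
    )


def evolve_k81(
    genome: AnnotatedGenome,
    branch_length: float,
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    strain_id: str | None = None,
) -> AnnotatedGenome:
    """Evolve every chromosome under the K81 model for ``branch_length``
    expected substitutions per site, partitioned among the three classes by
    ``fractions``. Sites are independent; N bases are left untouched."""
    p_ts, p_tv1, p_tv2 = k81_change_probs(branch_length, fractions)
    rng = np.random.default_rng(seed)
    code = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        code[base] = i
    new_chroms: dict[str, str] = {}
    for name in sorted(genome.chromosomes):
        arr = np.frombuffer(genome.chromosomes[name].encode(), dtype=np.uint8).copy()
        codes = code[arr]
        ok = codes != 255
        u = rng.random(arr.size)
        for threshold_lo, threshold_hi, table in (
            (0.0, p_ts, _TS),
            (p_ts, p_ts + p_tv1, _TV1),
            (p_ts + p_tv1, p_ts + p_tv1 + p_tv2, _TV2),
        ):
            sel = ok & (u >= threshold_lo) & (u < threshold_hi)
            arr[sel] = _BASES[table[codes[sel]]]
        new_chroms[name] = arr.tobytes().decode()
    derived = AnnotatedGenome(
        strain_id=strain_id or genome.strain_id,
        chromosomes=new_chroms,
        genes=list(genome.genes),
    )
    if strain_id:
        derived = derived.relabel_strain(strain_id)
    return derived


# -- shared block planting -------------------------------------------------


def plant_shared_block(
    strain_a: AnnotatedGenome,
    strain_b: AnnotatedGenome,
    focal: str,
    left: int,
    right: int,
) -> tuple[AnnotatedGenome, dict]:
    """Copy strain A's focal gene and ``left``/``right`` flanking gene
    sequences into strain B, creating an identical-by-state block there.

    Flanks are counted in strain A gene order on the focal chromosome
    (left = decreasing coordinates). Gene lengths must match between the
    strains (substitution-only divergence).
    """
    focal_a = strain_a.find_ortholog(focal)
    if focal_a is None:
        raise ConfigError(f"{strain_a.strain_id}: focal ortholog {focal} absent")
    on_chrom = strain_a.genes_on(focal_a.chromosome)
    idx = on_chrom.index(focal_a)
    if idx - left < 0 or idx + right >= len(on_chrom):
        raise ConfigError("block extends beyond the available flank")
    new_b = strain_b.copy()
    chroms = {n: bytearray(s.encode()) for n, s in new_b.chromosomes.items()}
    planted: list[str] = []
    for j in range(idx - left, idx + right + 1):
        gene_a = on_chrom[j]
        gene_b = new_b.find_ortholog(gene_a.ortholog_id)
        if gene_b is None:
            raise ConfigError(
                f"{strain_b.strain_id}: block ortholog {gene_a.ortholog_id} absent"
            )
        seq = strain_a.gene_sequence(gene_a)
        if len(seq) != gene_b.length:
            raise ConfigError(
                f"length mismatch for ortholog {gene_a.ortholog_id}"
            )
        if gene_b.strand == "-":
            seq = reverse_complement(seq)
        chroms[gene_b.chromosome][gene_b.start - 1 : gene_b.end] = seq.encode()
        planted.append(gene_a.ortholog_id)
    new_b.chromosomes = {n: bytes(s).decode() for n, s in chroms.items()}
    truth = {
        "strain_a": strain_a.strain_id,
        "strain_b": strain_b.strain_id,
        "left": left,
        "right": right,
        "orthologs": planted,
    }
    return new_b, truth


# -- qPCR simulation -------------------------------------------------------


@dataclass(frozen=True)
class QpcrSpec:
    """Planted relative expression design.

    ``fold_changes`` maps strain -> true target fold-change relative to the
    calibrator (which must map to 1.0). Reference-gene quantities are
    constant across strains; Ct noise is Gaussian in cycles.
    """

    fold_changes: tuple[tuple[str, float], ...] = (
        ("CAL1", 1.0),
        ("ANC2", 1.0),
        ("TRA1", 10.0),
        ("TRA2", 5.0),
    )
    calibrator: str = "CAL1"
    conditions: tuple[str, ...] = ("MBS", "noMBS")
    timepoints: tuple[int, ...] = (24, 48, 72, 96)
    replicates: int = 3
    noise_sd: float = 0.2
    target_gene: str = "SSU1"
    reference_genes: tuple[str, str] = ("ACT1", "RDN18")
    efficiencies: tuple[tuple[str, float], ...] = (
        ("SSU1", 2.0),
        ("ACT1", 2.0),
        ("RDN18", 2.0),
    )
    intercepts: tuple[tuple[str, float], ...] = (
        ("SSU1", 24.0),
        ("ACT1", 20.0),
        ("RDN18", 15.0),
    )
    dilutions: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)


def simulate_qpcr(spec: QpcrSpec, seed: int) -> tuple[QpcrDataset, dict]:
    """Ct tables from the planted design: Ct = intercept + slope·log10(q)
    + N(0, noise_sd), plus a standard-curve dilution series per gene."""
    folds = dict(spec.fold_changes)
    if abs(folds.get(spec.calibrator, 0.0) - 1.0) > 1e-12:
        raise ConfigError("calibrator fold-change must be 1.0")
    eff = dict(spec.efficiencies)
    intercept = dict(spec.intercepts)
    slope = {g: -1.0 / math.log10(e) for g, e in eff.items()}
    rng = np.random.default_rng(seed)
    rows = []
    genes = [spec.target_gene, *spec.reference_genes]
    for strain, fold in spec.fold_changes:
        for cond in spec.conditions:
            for tp in spec.timepoints:
                for gene in genes:
                    q = fold if gene == spec.target_gene else 1.0
                    base_ct = intercept[gene] + slope[gene] * math.log10(q)
                    for rep in range(1, spec.replicates + 1):
                        rows.append(
                            {
                                "strain": strain,
                                "condition": cond,
                                "timepoint": tp,
                                "gene": gene,
                                "replicate": rep,
                                "ct": base_ct + rng.normal(0.0, spec.noise_sd)
                                if spec.noise_sd > 0
                                else base_ct,
                            }
                        )
    std_rows = []
    for gene in genes:
        for dil in spec.dilutions:
            ct = intercept[gene] + slope[gene] * math.log10(dil)
            if spec.noise_sd > 0:
                ct += rng.normal(0.0, spec.noise_sd)
            std_rows.append({"gene": gene, "dilution": dil, "ct": ct})
    dataset = QpcrDataset(
        measurements=pd.DataFrame(rows),
        standards=pd.DataFrame(std_rows),
        target_gene=spec.target_gene,
        reference_genes=spec.reference_genes,
    )
    truth = {"fold_changes": folds, "calibrator": spec.calibrator}
    return dataset, truth


# -- drop-test simulation --------------------------------------------------


@dataclass(frozen=True)
class DropTestSpec:
    """Class tolerance means on the MBS grid.

    Each class is (label, mean, n strains, ceiling): per-strain maxima are
    drawn around the class mean and clipped at the ceiling — ancestral
    strains never grow past 0.2 g/L while translocated strains reach the
    top of the 0–0.4 g/L grid.
    """

    classes: tuple[tuple[str, float, int, float], ...] = (
        ("ancestral", 0.175, 52, 0.20),
        ("VII^XVI", 0.375, 10, 0.40),
        ("XI^XVI", 0.40, 1, 0.40),
    )
    noise_sd: float = 0.025
    grid: tuple[float, ...] = DEFAULT_GRID


def simulate_droptest(spec: DropTestSpec, seed: int) -> tuple[DropTestTable, dict]:
    """Each strain's max tolerated concentration is drawn around its class
    mean, discretized to the grid; scores decay from 6 toward 1 with
    concentration up to that maximum and are 0 above it."""
    rng = np.random.default_rng(seed)
    grid = np.asarray(spec.grid)
    prefix = {"ancestral": "ANC", "VII^XVI": "TVII", "XI^XVI": "TXI"}
    rows = []
    truth_means: dict[str, float] = {}
    for cls, mean, n, ceiling in spec.classes:
        if not (grid[0] <= mean <= grid[-1]):
            raise ConfigError(f"class mean {mean} outside grid")
        truth_means[cls] = mean
        for i in range(1, n + 1):
            draw = rng.normal(mean, spec.noise_sd) if spec.noise_sd > 0 else mean
            draw = min(draw, ceiling)
            max_c = float(grid[np.argmin(np.abs(grid - draw))])
            row = {"strain": f"{prefix.get(cls, cls)}{i:02d}", "promoter_class": cls}
            for conc in spec.grid:
                if conc <= max_c:
                    frac = conc / max_c if max_c > 0 else 0.0
                    row[_conc_col(conc)] = max(1, round(6 - 5 * frac))
                else:
                    row[_conc_col(conc)] = 0
            rows.append(row)
    table = DropTestTable(data=pd.DataFrame(rows), grid=spec.grid)
    return table, {"class_means": truth_means}


# -- full scenario ---------------------------------------------------------


@dataclass(frozen=True)
class StrainPlan:
    name: str
    branch_length: float = 0.02
    partner_chromosome: str | None = None  # None = ancestral promoter
    offset: int = 339
    microhomology: int = 8


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to emit a complete synthetic study."""

    seed: int = 17
    genome: SimulationConfig = field(default_factory=lambda: SimulationConfig(seed=17))
    strains: tuple[StrainPlan, ...] = (
        StrainPlan("ANC1"),
        StrainPlan("ANC2"),
        StrainPlan("ANC3"),
        StrainPlan("TRA1", partner_chromosome="chr1", offset=339, microhomology=8),
        StrainPlan("TRA2", partner_chromosome="chr1", offset=339, microhomology=8),
        StrainPlan("TRB1", partner_chromosome="chr2", offset=393, microhomology=4),
    )
    shared_block: tuple[str, str, int, int] | None = ("TRA1", "TRA2", 33, 21)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)
    droptest: DropTestSpec = field(default_factory=DropTestSpec)

    @staticmethod
    def from_yaml(path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seed = int(raw.get("seed", 17))
        genome = SimulationConfig(
            seed=seed,
            **{
                k: raw[k]
                for k in (
                    "n_chromosomes",
                    "genes_per_chromosome",
                    "gene_length",
                    "intergenic_length",
                    "focal_chromosome",
                    "focal_index",
                    "motif",
                    "motif_distance",
                )
                if k in raw
            },
        )
        strains = tuple(
            StrainPlan(
                name=s["name"],
                branch_length=float(s.get("branch_length", 0.02)),
                partner_chromosome=s.get("partner_chromosome"),
                offset=int(s.get("offset", 339)),
                microhomology=int(s.get("microhomology", 8)),
            )
            for s in raw.get("strains", [])
        ) or ScenarioConfig().strains
        block = raw.get("shared_block")
        return ScenarioConfig(
            seed=seed,
            genome=genome,
            strains=strains,
            shared_block=tuple(block) if block else None,
        )


@dataclass
class Scenario:
    config: ScenarioConfig
    reference: AnnotatedGenome
    strains: dict[str, AnnotatedGenome]
    orthologs: OrthologMap
    qpcr: QpcrDataset
    droptest: DropTestTable
    truth: dict


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full study: reference + strains (with planted
    rearrangements, divergence and shared block), qPCR and drop-test tables,
    and a truth table consistent with the emitted data."""
    root = np.random.default_rng(config.seed)
    sub = root.integers(0, 2**31 - 1, size=len(config.strains) + 4)
    reference, _ = simulate_reference(config.genome)
    focal = config.genome.focal_ortholog

    # The microhomology tract is an ancestral feature shared by the two
    # parental chromosomes, so every distinct translocation site gets one
    # site-specific tract planted into the reference before any strain is
    # derived; strains sharing a site then share its tract.
    sites: dict[tuple[str, int, int], TranslocationSpec] = {}
    site_rng = np.random.default_rng(int(sub[-3]))
    for plan in config.strains:
        if plan.partner_chromosome is None:
            continue
        key = (plan.partner_chromosome, plan.offset, plan.microhomology)
        if key not in sites:
            sites[key] = TranslocationSpec(
                partner_chromosome=plan.partner_chromosome,
                offset=plan.offset,
                microhomology=plan.microhomology,
                seed=int(site_rng.integers(0, 2**31 - 1)),
            )
            reference, _ = plant_microhomology(reference, focal, sites[key])

    truth: dict = {"focal_ortholog": focal, "strains": {}, "seed": config.seed}
    strains: dict[str, AnnotatedGenome] = {}
    for i, plan in enumerate(config.strains):
        base = reference
        entry: dict = {"variant_class": "ancestral"}
        if plan.partner_chromosome is not None:
            key = (plan.partner_chromosome, plan.offset, plan.microhomology)
            base, entry = apply_translocation(reference, focal, sites[key])
        strains[plan.name] = evolve_k81(
            base, plan.branch_length, seed=int(sub[i]), strain_id=plan.name
        )
        entry["branch_length"] = plan.branch_length
        truth["strains"][plan.name] = entry
    if config.shared_block is not None:
        a, b, left, right = config.shared_block
        strains[b], block_truth = plant_shared_block(
            strains[a], strains[b], focal, left, right
        )
        truth["shared_block"] = block_truth
    qpcr, qpcr_truth = simulate_qpcr(config.qpcr, int(sub[-2]))
    droptest, drop_truth = simulate_droptest(config.droptest, int(sub[-1]))
    truth["qpcr"] = qpcr_truth
    truth["droptest"] = drop_truth
    omap = build_ortholog_map([reference, *strains.values()])
    return Scenario(
        config=config,
        reference=reference,
        strains=strains,
        orthologs=omap,
        qpcr=qpcr,
        droptest=droptest,
        truth=truth,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Emit FASTA+GFF3 per strain, ortholog TSV, qPCR and drop-test TSVs and
    the truth-table JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, genome in (
        ("REF", scenario.reference),
        *scenario.strains.items(),
    ):
        write_annotated_genome(genome, out / f"{name}.fasta", out / f"{name}.gff3")
    write_ortholog_table(scenario.orthologs, out / "orthologs.tsv")
    scenario.qpcr.measurements.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
    scenario.qpcr.standards.to_csv(out / "qpcr_standards.tsv", sep="\t", index=False)
    scenario.droptest.data.to_csv(out / "droptest.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(scenario.truth, indent=2))
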