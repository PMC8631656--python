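"""Classify focal-gene promoter configurations and localize translocation junctions.

A strain's promoter is *ancestral* when the nearest upstream ortholog matches
the reference strain's, and *translocated* otherwise; for translocated strains
the junction is localized to base-pair resolution against the two parental
reference chromosomes, together with the microhomology tract that makes the
exact breakpoint ambiguous, and the retention status of a transcription-factor
binding motif (default the Fzf1p site 5'-CTATCA-3') in the ancestral promoter.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import AnnotatedGenome, GeneFeature, gene_start, reverse_complement

__all__ = [
    "MotifSpec",
    "GeneNeighborhood",
    "BreakpointCall",
    "RearrangementCall",
    "upstream_window",
    "extract_neighborhood",
    "classify_promoter",
    "locate_breakpoint",
    "motif_retention",
    "scan_collection",
    "calls_to_table",
    "write_calls",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifSpec:
    """IUPAC motif searched in promoter windows, optionally on both strands."""

    motif: str = "CTATCA"
    both_strands: bool = True

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        for ch in self.motif.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {ch!r}")

    def regex(self) -> re.Pattern[str]:
        return re.compile("".join(IUPAC[c] for c in self.motif.upper()))

    def regex_rc(self) -> re.Pattern[str]:
        rc = reverse_complement(self.motif.upper().replace("N", "N"))
        return re.compile("".join(IUPAC[c] for c in rc))


@dataclass
class GeneNeighborhood:
    """Genes flanking the focal gene on its coding strand, nearest first."""

    strain_id: str
    focal_ortholog: str
    focal_gene: GeneFeature
    upstream: list[GeneFeature]
    downstream: list[GeneFeature]
    intergenic_bp: int | None  # previous gene's nearest end -> focal start gap
    start_to_start_bp: int | None

    @property
    def upstream_ortholog(self) -> str | None:
        return self.upstream[0].ortholog_id if self.upstream else None


@dataclass
class BreakpointCall:
    """Junction localization result against two parental chromosomes."""

    status: str  # resolved | unresolved | complex
    offset: int | None = None  # focal-proximal edge, bp upstream of gene start
    interval: tuple[int, int] | None = None  # [lo, hi] bp upstream
    microhomology: str = ""


@dataclass
class RearrangementCall:
    strain_id: str
    variant_class: str  # ancestral | translocated | uncallable
    partner_chromosome: str | None = None
    upstream_ortholog: str | None = None
    breakpoint_offset: int | None = None
    ambiguity_interval: tuple[int, int] | None = None
    microhomology_seq: str = ""
    motif_status: str | None = None  # retained | lost | absent
    breakpoint_status: str | None = None
    intergenic_bp: int | None = None
    start_to_start_bp: int | None = None


# -- promoter geometry -----------------------------------------------------


def upstream_window(genome: AnnotatedGenome, feature: GeneFeature, w: int) -> str:
    """Promoter sequence of length <= w, 5'->3', ending at the base adjacent
    to the strand-aware gene start."""
    chrom = genome.chromosomes[feature.chromosome]
    if feature.strand == "+":
        lo = max(0, feature.start - 1 - w)
        return chrom[lo : feature.start - 1]
    hi = min(len(chrom), feature.end + w)
    return reverse_complement(chrom[feature.end : hi])


def extract_neighborhood(
    genome: AnnotatedGenome, focal: str, k: int = 5
) -> GeneNeighborhood:
    """Genes around the focal ortholog on its coding strand.

    The intergenic distance is (focal start) − (previous gene's nearest end)
    − 1 in bp; the start-to-start distance is |focal start − previous gene
    start| with strand-aware starts. Negative gaps (overlapping genes) are
    clamped to 0.
    """
    focal_gene = genome.find_ortholog(focal)
    if focal_gene is None:
        raise KeyError(f"{genome.strain_id}: focal ortholog {focal} absent")
    on_chrom = genome.genes_on(focal_gene.chromosome)
    idx = on_chrom.index(focal_gene)
    left = on_chrom[:idx][::-1]  # nearest first, decreasing coordinates
    right = on_chrom[idx + 1 :]
    if focal_gene.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    upstream = upstream[:k]
    downstream = downstream[:k]

    intergenic = start_to_start = None
    if upstream:
        prev = upstream[0]
        if focal_gene.strand == "+":
            intergenic = focal_gene.start - prev.end - 1
        else:
            intergenic = prev.start - focal_gene.end - 1
        intergenic = max(0, intergenic)
        start_to_start = abs(gene_start(focal_gene) - gene_start(prev))
    return GeneNeighborhood(
        strain_id=genome.strain_id,
        focal_ortholog=focal,
        focal_gene=focal_gene,
        upstream=upstream,
        downstream=downstream,
        intergenic_bp=intergenic,
        start_to_start_bp=start_to_start,
    )


def classify_promoter(
    neighborhood: GeneNeighborhood,
    reference_neighborhood: GeneNeighborhood,
    reference: AnnotatedGenome,
) -> RearrangementCall:
    """Ancestral iff the nearest upstream ortholog matches the reference's.

    For translocated strains the partner chromosome is the reference
    chromosome carrying the observed upstream ortholog ("unknown" when that
    ortholog is not annotated in the reference).
    """
    if neighborhood.focal_ortholog != reference_neighborhood.focal_ortholog:
        raise ValueError("neighborhoods do not share the focal ortholog")
    observed = neighborhood.upstream_ortholog
    expected = reference_neighborhood.upstream_ortholog
    call = RearrangementCall(
        strain_id=neighborhood.strain_id,
        variant_class="ancestral",
        upstream_ortholog=observed,
        intergenic_bp=neighborhood.intergenic_bp,
        start_to_start_bp=neighborhood.start_to_start_bp,
    )
    if observed == expected:
        return call
    call.variant_class = "translocated"
    partner = None
    if observed is not None:
        hit = reference.find_ortholog(observed)
        partner = hit.chromosome if hit is not None else "unknown"
    call.partner_chromosome = partner or "unknown"
    return call


# -- breakpoint localization ----------------------------------------------


def _anchor(window: str, parent: str, seed_len: int, from_end: str) -> int | None:
    """Map window coordinates onto a parent chromosome with an exact seed.

    Tries successive seed positions stepping inward from the chosen window
    end until a unique exact hit is found; returns the parent index of
    window position 0, or None.
    """
    w = len(window)
    step = max(1, seed_len // 3)
    positions = (
        range(w - seed_len, -1, -step)
        if from_end == "proximal"
        else range(0, w - seed_len + 1, step)
    )
    for j in list(positions)[:200]:
        seed = window[j : j + seed_len]
        q = parent.find(seed)
        if q < 0:
            continue
        if parent.find(seed, q + 1) >= 0:
            continue  # ambiguous seed, try another
        return q - j
    return None


def locate_breakpoint(
    window: str,
    parent_a: str,
    parent_b: str,
    seed_len: int = 20,
    min_gain: int = 10,
) -> BreakpointCall:
    """Localize the switch point between two parental chromosomes.

    ``window`` is the recombinant promoter sequence 5'->3' ending at the
    focal gene start; ``parent_a`` is the ancestral focal-chromosome
    sequence (which the focal-proximal side of the window should match) and
    ``parent_b`` the partner chromosome. Each parent is anchored into window
    coordinates with an exact seed, per-base match arrays are computed, and
    the junction is the changepoint maximizing

        (# parent-B matches distal of it) + (# parent-A matches proximal of it).

    The full argmax set is the ambiguity interval: with a planted k-bp
    microhomology and no divergence it spans exactly k bp. Offsets are
    reported in bp upstream of the focal gene start; the breakpoint offset
    is the interval's focal-proximal edge.
    """
    w = len(window)
    off_a = _anchor(window, parent_a, seed_len, "proximal")
    if off_a is None:
        return BreakpointCall(status="unresolved")
    off_b = _anchor(window, parent_b, seed_len, "distal")
    if off_b is None:
        return BreakpointCall(status="unresolved")

    def match_array(parent: str, off: int) -> np.ndarray:
        out = np.zeros(w, dtype=bool)
        lo = max(0, -off)
        hi = min(w, len(parent) - off)
        if hi <= lo:
            return out
        wa = np.frombuffer(window[lo:hi].encode(), dtype=np.uint8)
        pa = np.frombuffer(parent[lo + off : hi + off].encode(), dtype=np.uint8)
        out[lo:hi] = wa == pa
        return out

    match_a = match_array(parent_a, off_a)
    match_b = match_array(parent_b, off_b)

    # score(s) = sum(match_b[:s]) + sum(match_a[s:]) over switch points s=0..w
    cum_b = np.concatenate([[0], np.cumsum(match_b)])
    suf_a = np.concatenate([np.cumsum(match_a[::-1])[::-1], [0]])
    score = cum_b + suf_a
    best = int(score.max())
    if best - int(score[0]) < min_gain:
        return BreakpointCall(status="unresolved")
    # With a perfectly matching window (best == w) the maximal-score plateau
    # is exactly the microhomology tract. Under divergence, single-base
    # coincidences can perturb the optimum, so the ambiguity set tolerates a
    # 2-point score drop (the changepoint analogue of a 2-mismatch stop).
    margin = 0 if best == w else 2
    arg = np.flatnonzero(score >= best - margin)
    if np.any(np.diff(arg) > 100):
        return BreakpointCall(status="complex")
    s_min, s_max = int(arg[0]), int(arg[-1])
    lo, hi = w - s_max, w - s_min  # bp upstream of focal start
    return BreakpointCall(
        status="resolved",
        offset=lo,
        interval=(lo, hi),
        microhomology=window[s_min:s_max],
    )


# -- motif retention -------------------------------------------------------


def motif_retention(
    reference_window: str,
    motif: MotifSpec,
    breakpoint_offset: int | None,
) -> tuple[str, list[int]]:
    """Motif status of the ancestral promoter relative to a junction.

    Scans the ancestral reference promoter window (5'->3', ending at the
    focal gene start) for IUPAC matches; positions are reported as the bp
    offset upstream of the gene start of the match's most distal base.
    ``absent``: no match anywhere; for a strain with a junction at
    ``breakpoint_offset``, a match is retained only if it lies entirely on
    the focal-proximal side of the junction — ``lost`` otherwise.
    With no junction (ancestral strain) any match is retained.
    """
    w = len(reference_window)
    positions: list[int] = []
    patterns = [motif.regex()]
    if motif.both_strands:
        patterns.append(motif.regex_rc())
    for pat in patterns:
        for m in pat.finditer(reference_window):
            positions.append(w - m.start())  # distal-edge offset
    positions = sorted(set(positions))
    if not positions:
        return "absent", []
    if breakpoint_offset is None:
        return "retained", positions
    retained = any(p <= breakpoint_offset for p in positions)
    return ("retained" if retained else "lost"), positions


# -- collection scan -------------------------------------------------------


def scan_collection(
    genomes: list[AnnotatedGenome],
    reference: AnnotatedGenome,
    focal: str,
    motif: MotifSpec | None = None,
    window: int = 5000,
    k: int = 5,
) -> tuple[list[RearrangementCall], dict[str, int]]:
    """One rearrangement call per strain plus summary counts per class.

    Strains lacking the focal ortholog are reported as ``uncallable`` and
    excluded from the summary counts.
    """
    motif = motif or MotifSpec()
    ref_neigh = extract_neighborhood(reference, focal, k=k)
    ref_window = upstream_window(reference, ref_neigh.focal_gene, window)
    calls: list[RearrangementCall] = []
    summary: dict[str, int] = {}
    for genome in genomes:
        if genome.find_ortholog(focal) is None:
            calls.append(
                RearrangementCall(strain_id=genome.strain_id, variant_class="uncallable")
            )
            continue
        neigh = extract_neighborhood(genome, focal, k=k)
        call = classify_promoter(neigh, ref_neigh, reference)
        if call.variant_class == "translocated":
            strain_window = upstream_window(genome, neigh.focal_gene, window)
            parent_a = reference.chromosomes[ref_neigh.focal_gene.chromosome]
            bp = BreakpointCall(status="unresolved")
            if call.partner_chromosome in reference.chromosomes:
                parent_b = reference.chromosomes[call.partner_chromosome]
                bp = locate_breakpoint(strain_window, parent_a, parent_b)
            else:
                # fall back to the best-anchoring parent among all non-focal
                # reference chromosomes when the upstream gene is unannotated
                for name, parent_b in reference.chromosomes.items():
                    if name == ref_neigh.focal_gene.chromosome:
                        continue
                    trial = locate_breakpoint(strain_window, parent_a, parent_b)
                    if trial.status == "resolved":
                        bp, call.partner_chromosome = trial, name
                        break
            call.breakpoint_status = bp.status
            call.breakpoint_offset = bp.offset
            call.ambiguity_interval = bp.interval
            call.microhomology_seq = bp.microhomology
        status, _ = motif_retention(ref_window, motif, call.breakpoint_offset)
        if call.variant_class == "ancestral":
            status, _ = motif_retention(ref_window, motif, None)
        call.motif_status = status
        calls.append(call)
        key = (
            "ancestral"
            if call.variant_class == "ancestral"
            else f"translocated:{call.partner_chromosome}"
        )
        summary[key] = summary.get(key, 0) + 1
    return calls, summary


def calls_to_table(calls: list[RearrangementCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "strain": c.strain_id,
                "class": c.variant_class,
                "partner": c.partner_chromosome or "",
                "offset_bp": c.breakpoint_offset,
                "microhomology_len": len(c.microhomology_seq),
                "microhomology_seq": c.microhomology_seq,
                "motif_status": c.motif_status or "",
                "intergenic_bp": c.intergenic_bp,
                "start_to_start_bp": c.start_to_start_bp,
            }
        )
    return pd.DataFrame(rows)


def write_calls(
    calls: list[RearrangementCall],
    summary: dict[str, int],
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    calls_to_table(calls).to_csv(tsv_path, sep="\t", index=False)
    payload = {
        "summary": summary,
        "calls": [
            {
                "strain": c.strain_id,
                "class": c.variant_class,
                "partner": c.partner_chromosome,
                "upstream_ortholog": c.upstream_ortholog,
                "breakpoint_offset": c.breakpoint_offset,
                "ambiguity_interval": list(c.ambiguity_interval)
                if c.ambiguity_interval
                else None,
                "microhomology_seq": c.microhomology_seq,
                "motif_status": c.motif_status,
                "breakpoint_status": c.breakpoint_status,
                "intergenic_bp": c.intergenic_bp,
                "start_to_start_bp": c.start_to_start_bp,
            }
            for c in calls
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2))
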