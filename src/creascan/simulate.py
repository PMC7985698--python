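"""Synthetic promoters, planted motifs, DE tables and ortholog clusters.

Every pipeline stage can be exercised against known ground truth without any
genome download.  Promoter backgrounds are i.i.d. bases with a controllable
GC content; motif instances are planted by overwriting background bases (the
promoter length never changes), either as single sites or as adjacent pairs
with a bounded start-to-start distance, mirroring the tandem repressor-site
geometry the scanner is meant to detect.  Planted sites are recorded as
ground truth and are guaranteed to re-scan as matches.

All generators are deterministic given an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import IUPAC_SETS, DegenerateMotif
from .sequence_io import reverse_complement

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one planted motif instance."""

    gene_id: str
    motif_name: str
    start: int
    strand: str
    mode: str
    replaced: str  # background bases that were overwritten


PlantingTruth = dict[str, list[PlantedSite]]


@dataclass
class MotifPlanting:
    motif: DegenerateMotif
    prob: float
    mode: str = "single"
    max_gap: int | None = None


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic promoter/regulon scenario."""

    n_genes: int
    promoter_length: int = 1000
    gc_content: float = 0.5
    plantings: list[MotifPlanting] = field(default_factory=list)
    set_fraction: float = 0.0
    seed: int = 0


def _check_gc(gc_content: float) -> None:
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError(f"gc_content must be in [0, 1], got {gc_content}")


def generate_promoters(
    n_genes: int,
    length: int = 1000,
    gc_content: float = 0.5,
    seed: int = 0,
    prefix: str = "g",
) -> tuple[dict[str, str], PlantingTruth]:
    """i.i.d. background promoters: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    _check_gc(gc_content)
    if n_genes < 0 or length <= 0:
        raise ValueError("n_genes must be >= 0 and length > 0")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [
            (1 - gc_content) / 2,
            gc_content / 2,
            gc_content / 2,
            (1 - gc_content) / 2,
        ]
    )
    idx = rng.choice(4, size=n_genes * length, p=probs)
    text = _BASE_BYTES[idx].tobytes().decode("ascii")
    width = max(4, len(str(max(n_genes - 1, 0))))
    promoters = {
        f"{prefix}{i:0{width}d}": text[i * length : (i + 1) * length]
        for i in range(n_genes)
    }
    return promoters, {}


def _draw_instance(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    # Uniform over the IUPAC expansion (positions are independent).
    return "".join(
        sorted(IUPAC_SETS[ch])[rng.integers(len(IUPAC_SETS[ch]))]
        for ch in motif.pattern
    )


def _write_site(
    seq: str, start: int, instance: str, strand: str
) -> tuple[str, str]:
    written = instance if strand == "+" else reverse_complement(instance)
    replaced = seq[start : start + len(written)]
    return seq[:start] + written + seq[start + len(written) :], replaced


def plant_motif(
    promoters: Mapping[str, str],
    motif: DegenerateMotif,
    prob: float,
    mode: str = "single",
    max_gap: int | None = None,
    seed: int = 0,
    allow_overlap: bool = False,
    truth: PlantingTruth | None = None,
) -> tuple[dict[str, str], PlantingTruth]:
    """Plant motif instances into promoters with per-gene probability.

    ``mode`` "single" writes one instance at a uniform valid offset on a
    uniform strand; "adjacent_pair" writes two instances whose start-to-start
    distance is uniform on [motif length, max_gap] (non-overlapping by
    default; ``allow_overlap`` lowers the minimum distance to 1).  Returns an
    updated copy of the promoters and the accumulated truth.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob}")
    if mode not in ("single", "adjacent_pair"):
        raise ValueError(f"unknown planting mode {mode!r}")
    if mode == "adjacent_pair":
        if max_gap is None:
            raise ValueError("adjacent_pair planting requires max_gap")
        min_gap = 1 if allow_overlap else motif.length
        if max_gap < min_gap:
            raise ValueError(
                f"max_gap {max_gap} below minimum start distance {min_gap}"
            )
    rng = np.random.default_rng(seed)
    updated = dict(promoters)
    out: PlantingTruth = {k: list(v) for k, v in (truth or {}).items()}
    length = motif.length
    for gene_id in sorted(updated):
        if rng.random() >= prob:
            continue
        seq = updated[gene_id]
        if mode == "single":
            if len(seq) < length:
                raise ValueError(
                    f"promoter {gene_id!r} shorter than motif {motif.name!r}"
                )
            start = int(rng.integers(len(seq) - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            instance = _draw_instance(motif, rng)
            seq, replaced = _write_site(seq, start, instance, strand)
            out.setdefault(gene_id, []).append(
                PlantedSite(gene_id, motif.name, start, strand, mode, replaced)
            )
        else:
            if len(seq) < 2 * length or max_gap > len(seq) - length:
                raise ValueError(
                    f"promoter {gene_id!r} too short for a pair of "
                    f"{motif.name!r} with max_gap {max_gap}"
                )
            min_gap = 1 if allow_overlap else length
            distance = int(rng.integers(min_gap, max_gap + 1))
            start = int(rng.integers(len(seq) - length - distance + 1))
            for offset in (start, start + distance):
                strand = "+" if rng.random() < 0.5 else "-"
                instance = _draw_instance(motif, rng)
                seq, replaced = _write_site(seq, offset, instance, strand)
                out.setdefault(gene_id, []).append(
                    PlantedSite(
                        gene_id, motif.name, offset, strand, mode, replaced
                    )
                )
        updated[gene_id] = seq
    return updated, out


def generate_enrichment_scenario(
    n_set: int,
    n_bg: int,
    p_set: float,
    p_bg: float,
    motif: DegenerateMotif,
    mode: str = "single",
    seed: int = 0,
    length: int = 1000,
    gc_content: float = 0.5,
    max_gap: int | None = 100,
) -> tuple[dict[str, str], frozenset[str], PlantingTruth]:
    """Target-set genes planted at p_set, the other genes at p_bg.

    Returns (promoters for all n_set + n_bg genes, the target-set labels,
    the planting truth).  The full background for enrichment is all genes.
    """
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(2**31, size=4)]
    set_prom, _ = generate_promoters(
        n_set, length, gc_content, seed=seeds[0], prefix="set_g"
    )
    bg_prom, _ = generate_promoters(
        n_bg, length, gc_content, seed=seeds[1], prefix="bg_g"
    )
    gap = max_gap if mode == "adjacent_pair" else None
    set_prom, truth = plant_motif(
        set_prom, motif, p_set, mode=mode, max_gap=gap, seed=seeds[2]
    )
    bg_prom, truth = plant_motif(
        bg_prom, motif, p_bg, mode=mode, max_gap=gap, seed=seeds[3], truth=truth
    )
    promoters = {**set_prom, **bg_prom}
    return promoters, frozenset(set_prom), truth


def generate_de_table(
    n_genes: int,
    frac_up: float = 0.1,
    frac_down: float = 0.0,
    lfc_magnitude: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """DE table with known truth labels ("up", "down", "null").

    True effects are drawn as lfc_magnitude + |N(0, 0.5)| (so every true
    effect is at least the stated magnitude and is recovered by thresholding
    at any fold change <= 2^lfc_magnitude), with adjusted p uniform on
    [0, 0.01).  Null genes get log2fc ~ N(0, 0.3) and padj ~ Uniform(0, 1).
    """
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ValueError("invalid up/down fractions")
    rng = np.random.default_rng(seed)
    n_up = int(round(n_genes * frac_up))
    n_down = int(round(n_genes * frac_down))
    labels = ["up"] * n_up + ["down"] * n_down + ["null"] * (
        n_genes - n_up - n_down
    )
    rng.shuffle(labels)
    width = max(4, len(str(max(n_genes - 1, 0))))
    gene_ids = [f"d{i:0{width}d}" for i in range(n_genes)]
    lfc = np.empty(n_genes)
    padj = np.empty(n_genes)
    for i, label in enumerate(labels):
        if label == "null":
            lfc[i] = rng.normal(0.0, 0.3)
            padj[i] = rng.uniform(0.0, 1.0)
        else:
            magnitude = lfc_magnitude + abs(rng.normal(0.0, 0.5))
            lfc[i] = magnitude if label == "up" else -magnitude
            padj[i] = rng.uniform(0.0, 0.01)
    table = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "padj": padj}
    )
    truth = dict(zip(gene_ids, labels))
    return table, truth


def generate_clusters(
    n_species: int = 3,
    n_clusters: int = 100,
    genes_per_cluster: int = 1,
    orphan_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, frozenset[tuple[str, str]]], dict[str, list[str]]]:
    """Ortholog clusters: each species joins each cluster independently.

    A species contributes ``genes_per_cluster`` genes to a cluster with
    probability 1 - orphan_rate.  Returns (cluster map, per-species gene
    lists).  Clusters that end up with no members are kept (empty), so
    orphan_rate=1 yields an all-empty map.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0.0 <= orphan_rate <= 1.0:
        raise ValueError("orphan_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    clusters: dict[str, frozenset[tuple[str, str]]] = {}
    per_species: dict[str, list[str]] = {sp: [] for sp in species}
    for c in range(n_clusters):
        cid = f"c{c:04d}"
        members: set[tuple[str, str]] = set()
        for sp in species:
            if rng.random() < 1.0 - orphan_rate:
                for j in range(genes_per_cluster):
                    gene = f"{sp}_{cid}_{j}"
                    members.add((sp, gene))
                    per_species[sp].append(gene)
        clusters[cid] = frozenset(members)
    return clusters, per_species


def truth_to_frame(truth: PlantingTruth) -> pd.DataFrame:
    """Flatten a planting truth into a TSV-ready table."""
    rows = [
        {
            "gene_id": site.gene_id,
            "motif": site.motif_name,
            "start": site.start,
            "strand": site.strand,
            "mode": site.mode,
        }
        for gene_id in sorted(truth)
        for site in truth[gene_id]
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "motif", "start", "strand", "mode"]
    )
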