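"""Synthetic inputs with planted ground truth for every analysis stage.

Three generators:

- :func:`make_count_matrix` — orthogroup-by-species copy-number matrices whose
  per-group expected count changes linearly with distance-to-LCA
  (``Poisson(max(eps, baseline + beta * d))``), with planted contracting and
  expanding groups;
- :func:`make_toy_genomes` — a set of small syntenic genomes (FASTA + GFF3 +
  ortholog table) derived from one anchor genome, with planted per-species
  retention, decay (a degraded unannotated remnant left in place) and deletion
  (locus excised) events;
- :func:`make_tree` — ladder-topology Newick trees realizing requested
  tip-to-LCA distances.

Every generator is bit-reproducible under a fixed seed and returns a planted
truth manifest next to its data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synteny import Gene, GenomeAnnotation, OrthologTable
from .trends import CountMatrix

__all__ = [
    "VOLVOCINE_SPECIES",
    "DEFAULT_DISTANCES",
    "CountSynthConfig",
    "GenomeSynthConfig",
    "make_count_matrix",
    "make_toy_genomes",
    "make_tree",
]

#: Default six-species study system (anchor species first).
VOLVOCINE_SPECIES = (
    "Chlamydomonas",
    "Gonium",
    "Pandorina",
    "Yamagishiella",
    "Eudorina",
    "Volvox",
)

#: Default tip-to-LCA distances (substitutions/site), increasing along the
#: ladder from the unicellular anchor to the most derived multicellular tip.
DEFAULT_DISTANCES = {
    "Chlamydomonas": 0.02,
    "Gonium": 0.10,
    "Pandorina": 0.18,
    "Yamagishiella": 0.26,
    "Eudorina": 0.34,
    "Volvox": 0.42,
}

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountSynthConfig:
    """Planted-slope count-matrix generator settings.

    ``planted`` lists (fraction, slope beta) pairs; the sign of beta marks
    contraction (negative) or expansion (positive).  When omitted, 2% of
    groups are planted contracting and 2% expanding at the reference effect
    size ``|beta| * range(d) = 5 * sqrt(baseline_mean)`` — a contraction that
    runs a large multi-copy family from roughly ``baseline_mean`` copies to
    zero across the sampled distance range.
    """

    n_groups: int = 5000
    distances: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCES)
    )
    baseline_mean: float = 25.0
    planted: list[tuple[float, float]] | None = None
    mean_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.distances) < 2:
            raise ValueError("need at least 2 species")
        if self.planted is None:
            d = np.array(list(self.distances.values()))
            beta = 5.0 * np.sqrt(self.baseline_mean) / np.ptp(d)
            self.planted = [(0.02, -beta), (0.02, beta)]
        if sum(f for f, _ in self.planted) > 1.0:
            raise ValueError("planted fractions must sum to at most 1")


def make_count_matrix(config: CountSynthConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Sample a count matrix with planted linear trends; returns (matrix, truth).

    ``truth`` has one row per group with its true slope and planted status.
    """
    rng = np.random.default_rng(config.seed)
    species = list(config.distances)
    d = np.array([config.distances[s] for s in species])
    n = config.n_groups
    betas = np.zeros(n)
    status = np.array(["neutral"] * n, dtype=object)
    start = 0
    for frac, beta in config.planted:
        k = int(round(frac * n))
        betas[start : start + k] = beta
        status[start : start + k] = "contracting" if beta < 0 else "expanding"
        start += k
    means = np.maximum(config.mean_floor, config.baseline_mean + betas[:, None] * d[None, :])
    counts = rng.poisson(means)
    group_ids = [f"OG{i:05d}" for i in range(n)]
    matrix = CountMatrix(pd.DataFrame(counts, index=group_ids, columns=species))
    truth = pd.DataFrame(
        {"group_id": group_ids, "true_beta": betas, "planted_status": status}
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# trees


def make_tree(distances: dict[str, float]) -> str:
    """Rooted ladder-topology Newick realizing given tip-to-LCA distances.

    Species are nested in order of increasing distance:
    ``(A,(B,(C,(D,(E,F)))));`` with internal edges of length
    ``min(d)/(2 n)`` and tip branches chosen so each tip's path from the root
    equals its requested distance.
    """
    if len(distances) < 2:
        raise ValueError("need at least 2 species")
    if any(v < 0 for v in distances.values()):
        raise ValueError("distances must be non-negative")
    items = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    e = min(v for _, v in items) / (2 * n)
    depths = list(range(n - 1)) + [n - 2] if n > 2 else [0, 0]
    tips = []
    for (sp, dist), depth in zip(items, depths):
        b = dist - depth * e
        if b < 0:
            raise ValueError(f"inconsistent distances: negative branch for {sp}")
        tips.append((sp, b))
    if n == 2:
        return f"({tips[0][0]}:{tips[0][1]:.10g},{tips[1][0]}:{tips[1][1]:.10g});"
    newick = f"{tips[-2][0]}:{tips[-2][1]:.10g},{tips[-1][0]}:{tips[-1][1]:.10g}"
    for sp, b in reversed(tips[1:-2]):
        newick = f"{sp}:{b:.10g},({newick}):{e:.10g}"
    return f"({tips[0][0]}:{tips[0][1]:.10g},({newick}):{e:.10g});"


# ---------------------------------------------------------------------------
# toy genomes


@dataclass
class GenomeSynthConfig:
    """Toy syntenic-genome generator settings.

    The anchor species (first in ``species``) carries the reference genome:
    random stop-free ORFs separated by random intergenic spacers.  Each other
    species copies the anchor gene order, applies neutral per-site
    substitutions at ``neutral_rate``, then applies its planted events.

    ``events`` maps (anchor_gene_id, species) to ``retain`` / ``decay`` /
    ``delete``.  When omitted, a default table is drawn: even-indexed genes
    and chromosome-end genes are retained in every species (guaranteeing
    mappable syntenic flanks for every tested locus), the remaining interior
    genes draw an event per species from ``event_probs``.
    """

    species: tuple[str, ...] = VOLVOCINE_SPECIES
    n_chromosomes: int = 2
    genes_per_chromosome: int = 30
    gene_length: int = 300  # codons, start and stop included
    intergenic_length: int = 150
    neutral_rate: float = 0.0  # substitutions/site on each derived species
    remnant_fraction: float = 0.6
    n_frameshifts: int = 2
    n_premature_stops: int = 2
    event_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    events: dict[tuple[str, str], str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need an anchor and at least one target species")
        if not 0.0 < self.remnant_fraction < 1.0:
            raise ValueError("remnant_fraction must be in (0, 1)")
        if not 0.0 <= self.neutral_rate < 1.0:
            raise ValueError("neutral_rate must be in [0, 1)")
        if self.gene_length < 3:
            raise ValueError("gene_length must be at least 3 codons")
        if abs(sum(self.event_probs) - 1.0) > 1e-9:
            raise ValueError("event_probs must sum to 1")

    @property
    def anchor_species(self) -> str:
        return self.species[0]


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_CODONS[i] for i in body) + _STOPS[rng.integers(3)]


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0 or not seq:
        return seq
    idx = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    vals = code[idx]
    hit = (rng.random(len(seq)) < rate) & (vals >= 0)
    shifted = (vals[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    out = np.array(list(seq))
    out[hit] = np.array(list("ACGT"))[shifted]
    return "".join(out)


def _decay_remnant(gene_seq: str, config: GenomeSynthConfig, rng: np.random.Generator) -> str:
    """Pseudogenize: truncate, inject frameshifts and premature stops."""
    keep = max(3, int(round(config.remnant_fraction * len(gene_seq))))
    remnant = list(gene_seq[:keep])
    n_codons = len(remnant) // 3
    stop_codons = rng.choice(max(1, n_codons - 1), size=min(config.n_premature_stops, max(1, n_codons - 1)), replace=False)
    for c in stop_codons:
        remnant[3 * c : 3 * c + 3] = list(_STOPS[rng.integers(3)])
    for _ in range(config.n_frameshifts):
        if len(remnant) > 4:
            del remnant[int(rng.integers(1, len(remnant) - 1))]
    return "".join(remnant)


def _default_events(config: GenomeSynthConfig, rng: np.random.Generator) -> dict:
    events: dict[tuple[str, str], str] = {}
    labels = ("retain", "decay", "delete")
    probs = np.array(config.event_probs)
    for c in range(config.n_chromosomes):
        for i in range(config.genes_per_chromosome):
            gid = _anchor_gene_id(config, c, i)
            guarded = i % 2 == 0 or i == config.genes_per_chromosome - 1
            for sp in config.species[1:]:
                if guarded:
                    events[(gid, sp)] = "retain"
                else:
                    events[(gid, sp)] = labels[rng.choice(3, p=probs)]
    return events


def _anchor_gene_id(config: GenomeSynthConfig, chrom: int, idx: int) -> str:
    return f"{config.anchor_species}_chr{chrom + 1}_g{idx:03d}"


def make_toy_genomes(config: GenomeSynthConfig) -> dict:
    """Generate syntenic toy genomes with planted loss events.

    Returns a dict with ``annotations`` (species -> GenomeAnnotation),
    ``ortholog_table``, ``truth`` (anchor_gene x species event table),
    ``groups`` (group id per anchor gene) and ``events``.
    """
    rng = np.random.default_rng(config.seed)
    anchor = config.anchor_species
    # anchor reference material: ORFs and spacers, reused by every species
    orfs: dict[tuple[int, int], str] = {}
    spacers: dict[tuple[int, int], str] = {}
    for c in range(config.n_chromosomes):
        for i in range(config.genes_per_chromosome):
            orfs[(c, i)] = _random_orf(config.gene_length, rng)
        for i in range(config.genes_per_chromosome + 1):
            spacers[(c, i)] = _random_dna(config.intergenic_length, rng)
    events = config.events if config.events is not None else _default_events(config, rng)
    for (gid, sp), ev in events.items():
        if sp not in config.species[1:]:
            raise ValueError(f"event for unknown species {sp}")
        if ev not in ("retain", "decay", "delete"):
            raise ValueError(f"unknown event {ev}")
    known_ids = {
        _anchor_gene_id(config, c, i)
        for c in range(config.n_chromosomes)
        for i in range(config.genes_per_chromosome)
    }
    bad = {g for g, _ in events} - known_ids
    if bad:
        raise ValueError(f"events reference unknown genes: {sorted(bad)}")

    annotations: dict[str, GenomeAnnotation] = {}
    ortho_rows = []
    truth_rows = []
    group_of_anchor: dict[str, str] = {}
    group_counter = 0
    for c in range(config.n_chromosomes):
        for i in range(config.genes_per_chromosome):
            group_of_anchor[_anchor_gene_id(config, c, i)] = f"OG{group_counter:04d}"
            group_counter += 1

    for sp_index, sp in enumerate(config.species):
        rate = 0.0 if sp == anchor else config.neutral_rate
        genes: list[Gene] = []
        seqs: dict[str, str] = {}
        for c in range(config.n_chromosomes):
            chrom = f"{sp}_chr{c + 1}"
            parts: list[str] = []
            pos = 0
            for i in range(config.genes_per_chromosome):
                spacer = _mutate(spacers[(c, i)], rate, rng)
                parts.append(spacer)
                pos += len(spacer)
                anchor_id = _anchor_gene_id(config, c, i)
                event = "retain" if sp == anchor else events.get((anchor_id, sp), "retain")
                gene_seq = _mutate(orfs[(c, i)], rate, rng)
                if event == "retain":
                    gene_id = anchor_id if sp == anchor else f"{sp}_chr{c + 1}_g{i:03d}"
                    genes.append(Gene(gene_id, chrom, pos + 1, pos + len(gene_seq), "+"))
                    parts.append(gene_seq)
                    pos += len(gene_seq)
                    ortho_rows.append(
                        {"group_id": group_of_anchor[anchor_id], "species": sp, "gene_id": gene_id}
                    )
                elif event == "decay":
                    remnant = _mutate(_decay_remnant(orfs[(c, i)], config, rng), rate, rng)
                    parts.append(remnant)
                    pos += len(remnant)
                else:  # delete: locus excised, flanking spacers splice together
                    pass
                if sp != anchor:
                    truth_rows.append(
                        {"anchor_gene": anchor_id, "species": sp, "event": event}
                    )
            tail = _mutate(spacers[(c, config.genes_per_chromosome)], rate, rng)
            parts.append(tail)
            seqs[chrom] = "".join(parts)
        annotations[sp] = GenomeAnnotation(genes, seqs)

    table = OrthologTable(pd.DataFrame(ortho_rows))
    truth = pd.DataFrame(truth_rows)
    return {
        "annotations": annotations,
        "ortholog_table": table,
        "truth": truth,
        "groups": group_of_anchor,
        "events": events,
        "config": config,
    }
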