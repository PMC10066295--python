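"""Synteny-anchored classification of gene loss: retained / decayed / deleted.

Anchor-species genes from contracting orthologous groups are located in each
target genome through their *syntenic neighborhood*: the genes immediately up-
and downstream of the anchor locus.  Orthologs of the neighborhood delimit a
target genomic interval; the anchor sequence is then searched against that
interval with the translated six-frame engine (:mod:`volvoloss.tsearch`).

Per target species each anchor locus is called:

- ``retained``        — the ortholog table lists a target-species member of
                        the anchor's group (no sequence check);
- ``decayed``         — no ortholog, but the syntenic interval contains a
                        translated hit with E below threshold (a gene remnant:
                        pseudogenization in place);
- ``deleted``         — no ortholog and no qualifying hit although the
                        syntenic interval is intact (locus excised);
- ``non_informative`` — the syntenic neighborhood cannot be mapped to a
                        single target interval (broken or lost synteny).

Cross-species patterns are binned by the subset of species with a loss; a
pattern is *cryptic* when that subset is not a single monophyletic clade of
the species tree (it would require more than one loss event under parsimony).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .tsearch import ScoringScheme, SearchHit, search

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "OrthologTable",
    "SyntenicNeighborhood",
    "LocusCall",
    "LossPattern",
    "select_anchor_loci",
    "build_neighborhood",
    "map_neighborhood",
    "call_locus",
    "classify_patterns",
    "summarize_events",
    "chisq_uniform",
    "classify_losses",
]

CALLS = ("retained", "decayed", "deleted", "non_informative")
LOSS_CALLS = ("decayed", "deleted")


@dataclass(frozen=True)
class Gene:
    """One annotated gene: 1-based closed coordinates, strand + or -."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates for {self.id}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


class GenomeAnnotation:
    """Gene annotation plus genome sequence for one species."""

    def __init__(self, genes: list[Gene], seqs: dict[str, str]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValueError(f"duplicate gene id {g.id}")
            if g.chrom in seqs and g.end > len(seqs[g.chrom]):
                raise ValueError(f"{g.id} extends past end of {g.chrom}")
            self.genes[g.id] = g
        self.seqs = dict(seqs)
        self._order: dict[str, list[str]] = {}
        by_chrom: dict[str, list[Gene]] = defaultdict(list)
        for g in self.genes.values():
            by_chrom[g.chrom].append(g)
        for chrom, gs in by_chrom.items():
            self._order[chrom] = [g.id for g in sorted(gs, key=lambda g: g.start)]

    def genes_on(self, chrom: str) -> list[str]:
        """Gene ids on a chromosome in genomic order."""
        return list(self._order.get(chrom, []))

    def gene_sequence(self, gene_id: str) -> str:
        g = self.genes[gene_id]
        seq = self.seqs[g.chrom][g.start - 1 : g.end]
        if g.strand == "-":
            seq = _revcomp(seq)
        return seq

    def interval_sequence(self, chrom: str, start: int, end: int) -> str:
        """Sequence of a 1-based closed interval; empty when start > end."""
        if start > end:
            return ""
        return self.seqs[chrom][start - 1 : end]

    # --- plain-text I/O -----------------------------------------------------

    @classmethod
    def from_files(cls, fasta_path, gff3_path) -> "GenomeAnnotation":
        from Bio import SeqIO
        import gffutils

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        db = gffutils.create_db(
            str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = [
            Gene(f.id, f.seqid, f.start, f.end, f.strand if f.strand in "+-" else "+")
            for f in db.features_of_type("gene")
        ]
        return cls(genes, seqs)

    def to_files(self, fasta_path, gff3_path, species: str = "synthetic") -> None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.seqs):
                fh.write(f"##sequence-region {chrom} 1 {len(self.seqs[chrom])}\n")
            for chrom in sorted(self._order):
                for gid in self._order[chrom]:
                    g = self.genes[gid]
                    fh.write(
                        f"{g.chrom}\t{species}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
                    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class OrthologTable:
    """group_id -> species -> gene ids, from a long-format table."""

    def __init__(self, records: pd.DataFrame):
        required = {"group_id", "species", "gene_id"}
        if not required <= set(records.columns):
            raise ValueError(f"ortholog table needs columns {sorted(required)}")
        self.records = records.reset_index(drop=True)
        self._members: dict[tuple[str, str], list[str]] = defaultdict(list)
        self._group_of: dict[tuple[str, str], str] = {}
        for row in self.records.itertuples(index=False):
            self._members[(row.group_id, row.species)].append(row.gene_id)
            self._group_of[(row.species, row.gene_id)] = row.group_id

    @classmethod
    def from_tsv(cls, path) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @property
    def group_ids(self) -> list[str]:
        return sorted(set(self.records["group_id"]))

    def members(self, group_id: str, species: str) -> list[str]:
        return list(self._members.get((group_id, species), []))

    def group_of(self, species: str, gene_id: str) -> str | None:
        return self._group_of.get((species, gene_id))

    def has_ortholog(self, group_id: str, species: str) -> bool:
        return bool(self._members.get((group_id, species)))


@dataclass
class SyntenicNeighborhood:
    """Flanking genes of an anchor locus, ordered moving away from it."""

    anchor_gene: str
    upstream: list[str]
    downstream: list[str]
    window: int


@dataclass
class LocusCall:
    anchor_gene: str
    target_species: str
    call: str
    best_hit: SearchHit | None = None
    interval: tuple[str, int, int] | None = None

    def __post_init__(self):
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call}")


@dataclass
class LossPattern:
    anchor_gene: str
    calls: dict[str, str]  # species -> call
    bin: tuple[str, ...]  # species with a loss, sorted
    cryptic: bool
    cluster: str  # retained_all | decayed_cluster | deleted_cluster


# ---------------------------------------------------------------------------


def select_anchor_loci(
    table: OrthologTable,
    anchor_annot: GenomeAnnotation,
    contracting_ids: set[str] | list[str],
    chromosome_ids: set[str] | list[str],
    anchor_species: str,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Anchor-species genes of contracting groups located on chromosomes.

    Genes on unplaced scaffolds (not in ``chromosome_ids``) are filtered and
    reported with a reason, mirroring the exclusion of loci not assembled into
    chromosomes.
    """
    known = set(table.group_ids)
    unknown = set(contracting_ids) - known
    if unknown:
        raise ValueError(f"unknown group ids: {sorted(unknown)}")
    chromosome_ids = set(chromosome_ids)
    selected, filtered = [], []
    for gid in sorted(contracting_ids):
        for gene_id in table.members(gid, anchor_species):
            gene = anchor_annot.genes.get(gene_id)
            if gene is None:
                filtered.append((gene_id, "not_in_annotation"))
            elif gene.chrom not in chromosome_ids:
                filtered.append((gene_id, "unplaced_scaffold"))
            else:
                selected.append(gene_id)
    return selected, filtered


def build_neighborhood(
    anchor_gene: str,
    annot: GenomeAnnotation,
    window: int = 5,
) -> SyntenicNeighborhood:
    """Up to ``window`` genes on each side of the anchor, in chromosomal
    order moving away from it; truncated at chromosome ends."""
    if window < 1:
        raise ValueError("window must be >= 1")
    gene = annot.genes.get(anchor_gene)
    if gene is None:
        raise KeyError(f"anchor gene {anchor_gene} not in annotation")
    order = annot.genes_on(gene.chrom)
    i = order.index(anchor_gene)
    upstream = order[max(0, i - window) : i][::-1]  # nearest first
    downstream = order[i + 1 : i + 1 + window]
    return SyntenicNeighborhood(anchor_gene, upstream, downstream, window)


def map_neighborhood(
    nbhd: SyntenicNeighborhood,
    table: OrthologTable,
    anchor_species: str,
    target_species: str,
    target_annot: GenomeAnnotation,
) -> tuple[str, int, int] | None:
    """Locate the target-genome interval bracketed by neighborhood orthologs.

    Requires at least one upstream and one downstream neighborhood ortholog on
    a single target scaffold, with the two flank groups separable along the
    scaffold (all upstream orthologs on one side of all downstream ones —
    strand and within-side order are ignored, tolerating local inversions).
    Returns the 1-based closed interval between the innermost flanking
    orthologs, intergenic sequence included, or ``None`` when synteny is
    broken.  A negative-length interval (abutting flanks) is returned with
    start = end + 1 and denotes an empty searchable region.
    """

    def target_orthologs(gene_ids: list[str]) -> list[Gene]:
        out = []
        for gid in gene_ids:
            group = table.group_of(anchor_species, gid)
            if group is None:
                continue
            for tg in table.members(group, target_species):
                g = target_annot.genes.get(tg)
                if g is not None:
                    out.append(g)
        return out

    ups = target_orthologs(nbhd.upstream)
    downs = target_orthologs(nbhd.downstream)
    if not ups or not downs:
        return None
    candidates = []
    for chrom in {g.chrom for g in ups} & {g.chrom for g in downs}:
        u = [g for g in ups if g.chrom == chrom]
        d = [g for g in downs if g.chrom == chrom]
        if max(g.end for g in u) < min(g.start for g in d):
            left, right = u, d
        elif max(g.end for g in d) < min(g.start for g in u):
            left, right = d, u
        else:
            continue  # interleaved flanks: order incompatible
        inner_left = max(g.end for g in left)
        inner_right = min(g.start for g in right)
        candidates.append((len(u) + len(d), chrom, inner_left + 1, inner_right - 1))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, chrom, start, end = candidates[0]
    return chrom, start, end


def call_locus(
    anchor_gene_dna: str,
    target_annot: GenomeAnnotation | None,
    target_interval: tuple[str, int, int] | None,
    ortholog_present: bool,
    threshold: float = 1e-5,
    scoring: ScoringScheme | None = None,
) -> LocusCall:
    """Classify one anchor locus in one target species.

    ``retained`` short-circuits on ortholog presence; otherwise an unmappable
    neighborhood yields ``non_informative``; otherwise the anchor sequence is
    searched against the interval — a qualifying translated hit means
    ``decayed`` (remnant present), none means ``deleted``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ortholog_present:
        return LocusCall("", "", "retained", None, target_interval)
    if target_interval is None:
        return LocusCall("", "", "non_informative", None, None)
    if not anchor_gene_dna:
        raise ValueError("anchor gene sequence is empty")
    chrom, start, end = target_interval
    subject = target_annot.interval_sequence(chrom, start, end)
    hits: list[SearchHit] = []
    if len(subject) >= 3:
        hits = search(anchor_gene_dna, subject, scoring=scoring, threshold=threshold)
    if hits:
        best = hits[0]
        # shift subject span from interval-local to scaffold coordinates
        best.subject_span = (
            best.subject_span[0] + start - 1,
            best.subject_span[1] + start - 1,
        )
        return LocusCall("", "", "decayed", best, target_interval)
    return LocusCall("", "", "deleted", None, target_interval)


def _is_clade(tree: dendropy.Tree, subset: set[str], universe: set[str]) -> bool:
    """True if ``subset`` is exactly the leaf set (restricted to ``universe``)
    below its MRCA — i.e. one loss event suffices under parsimony."""
    if len(subset) == 1:
        return True
    mrca = tree.mrca(taxon_labels=sorted(subset))
    below = {l.taxon.label for l in mrca.leaf_iter()} & universe
    return below == subset


def classify_patterns(
    calls: list[LocusCall],
    species_tree: dendropy.Tree | str,
) -> list[LossPattern]:
    """Bin per-locus calls across species and flag cryptic patterns.

    Every anchor gene must carry a call for every target species.  The bin is
    the species subset with ``decayed``/``deleted`` calls; the pattern is
    cryptic unless that subset is empty or forms a single monophyletic clade
    of the species tree.
    """
    if not isinstance(species_tree, dendropy.Tree):
        species_tree = dendropy.Tree.get(
            data=str(species_tree), schema="newick", rooting="force-rooted"
        )
    species_tree.is_rooted = True
    by_gene: dict[str, dict[str, str]] = defaultdict(dict)
    species: set[str] = set()
    for c in calls:
        by_gene[c.anchor_gene][c.target_species] = c.call
        species.add(c.target_species)
    patterns = []
    for gene in sorted(by_gene):
        gene_calls = by_gene[gene]
        missing = species - set(gene_calls)
        if missing:
            raise ValueError(f"{gene} lacks calls for {sorted(missing)}")
        lost = {s for s, c in gene_calls.items() if c in LOSS_CALLS}
        if not lost:
            cryptic = False
        else:
            cryptic = not _is_clade(species_tree, lost, species)
        if not lost:
            cluster = "retained_all"
        elif any(gene_calls[s] == "decayed" for s in lost):
            cluster = "decayed_cluster"
        else:
            cluster = "deleted_cluster"
        patterns.append(
            LossPattern(gene, gene_calls, tuple(sorted(lost)), cryptic, cluster)
        )
    return patterns


def summarize_events(patterns: list[LossPattern]) -> dict[str, pd.DataFrame]:
    """Per-species call counts, cross-species cluster counts, pattern bins."""
    species = sorted({s for p in patterns for s in p.calls})
    per_species = pd.DataFrame(0, index=species, columns=list(CALLS))
    for p in patterns:
        for s, c in p.calls.items():
            per_species.loc[s, c] += 1
    clusters = pd.Series(
        [p.cluster for p in patterns], dtype="object"
    ).value_counts().reindex(
        ["retained_all", "decayed_cluster", "deleted_cluster"], fill_value=0
    )
    bins = pd.DataFrame(
        [
            {
                "anchor_gene": p.anchor_gene,
                "bin": "+".join(p.bin) if p.bin else "none",
                "cryptic": p.cryptic,
                "cluster": p.cluster,
            }
            for p in patterns
        ]
    )
    bin_hist = (
        bins.groupby(["bin", "cryptic"]).size().rename("n_loci").reset_index()
        if len(bins)
        else pd.DataFrame(columns=["bin", "cryptic", "n_loci"])
    )
    return {
        "per_species": per_species,
        "clusters": clusters.to_frame("n_loci"),
        "patterns": bins,
        "bin_histogram": bin_hist,
    }


def chisq_uniform(observed) -> dict:
    """Chi-square goodness-of-fit test against a uniform expectation.

    Expected count is total/n_cells in every cell; df = n_cells - 1; no
    continuity correction.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 cells")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    statistic, p_value = stats.chisquare(obs)
    return {
        "statistic": float(statistic),
        "df": int(obs.size - 1),
        "p_value": float(p_value),
    }


# ---------------------------------------------------------------------------
# end-to-end driver


def classify_losses(
    anchor_species: str,
    annotations: dict[str, GenomeAnnotation],
    table: OrthologTable,
    contracting_ids: set[str] | list[str],
    species_tree: dendropy.Tree | str | None = None,
    chromosome_ids: set[str] | None = None,
    window: int = 5,
    threshold: float = 1e-5,
    scoring: ScoringScheme | None = None,
) -> dict:
    """Run the full loss classification over all anchors and target species.

    Returns calls, patterns (when a tree is given), summary tables and the
    chi-square tests on loss-type counts.
    """
    anchor_annot = annotations[anchor_species]
    if chromosome_ids is None:
        chromosome_ids = set(anchor_annot.seqs)
    targets = sorted(s for s in annotations if s != anchor_species)
    anchors, filtered = select_anchor_loci(
        table, anchor_annot, contracting_ids, chromosome_ids, anchor_species
    )
    calls: list[LocusCall] = []
    for gene_id in anchors:
        nbhd = build_neighborhood(gene_id, anchor_annot, window)
        group = table.group_of(anchor_species, gene_id)
        dna = anchor_annot.gene_sequence(gene_id)
        for sp in targets:
            present = table.has_ortholog(group, sp)
            interval = None
            if not present:
                interval = map_neighborhood(nbhd, table, anchor_species, sp, annotations[sp])
            c = call_locus(dna, annotations[sp], interval, present, threshold, scoring)
            c.anchor_gene = gene_id
            c.target_species = sp
            calls.append(c)
    out: dict = {"calls": calls, "filtered_anchors": filtered, "window": window}
    calls_df = pd.DataFrame(
        [
            {
                "anchor_gene": c.anchor_gene,
                "species": c.target_species,
                "call": c.call,
                "best_hit_evalue": c.best_hit.evalue if c.best_hit else np.nan,
                "interval": (
                    f"{c.interval[0]}:{c.interval[1]}-{c.interval[2]}" if c.interval else ""
                ),
                "window": window,
            }
            for c in calls
        ]
    )
    out["calls_table"] = calls_df
    if species_tree is not None:
        patterns = classify_patterns(calls, species_tree)
        out["pattern_objects"] = patterns
        out.update(summarize_events(patterns))  # adds the "patterns" table
        decay = int((calls_df["call"] == "decayed").sum())
        deleted = int((calls_df["call"] == "deleted").sum())
        if decay + deleted > 0:
            out["chisq_loss_type"] = chisq_uniform([decay, deleted])
    return out
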