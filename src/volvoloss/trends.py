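"""Gene-family contraction/expansion detection from copy-number trends.

For every orthologous group (or Pfam domain, transcription-factor or
protein-kinase family), the per-species gene copy number is regressed by
ordinary least squares on the species' phylogenetic distance to the in-group
last common ancestor (LCA).  The fitted slope is the family's *rate of gene
number change* (copies per unit branch length).  Rates across all eligible
groups are then subjected to quartile (Tukey-fence) outlier analysis: groups
whose rate falls below ``Q1 - 1.5 IQR`` are called contracting, above
``Q3 + 1.5 IQR`` expanding.

Eligibility mirrors the analysis this implements: a group enters the
regression only if it has a nonzero count in at least two species and its
counts are not identical across species.  Species with zero copies still
contribute their (distance, 0) point to the fit — sparsity is handled by
eligibility, not by dropping data.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GroupRate",
    "TrendResult",
    "distances_from_tree",
    "filter_groups",
    "ols_rate",
    "tukey_outliers",
    "classify_trends",
]


@dataclass
class CountMatrix:
    """Integer copy-number matrix: rows = groups, columns = species."""

    counts: pd.DataFrame  # index: group ids, columns: species

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("group ids must be unique")
        if df.columns.has_duplicates:
            raise ValueError("species names must be unique")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class GroupRate:
    group_id: str
    slope: float
    intercept: float
    status: str  # expanding | contracting | neutral | excluded
    reason_excluded: str | None = None


@dataclass
class TrendResult:
    rates: list[GroupRate]
    lower_fence: float
    upper_fence: float

    @property
    def contracting(self) -> list[str]:
        return [r.group_id for r in self.rates if r.status == "contracting"]

    @property
    def expanding(self) -> list[str]:
        return [r.group_id for r in self.rates if r.status == "expanding"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_id": r.group_id,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "status": r.status,
                    "reason_excluded": r.reason_excluded or "",
                }
                for r in self.rates
            ]
        )

    def summary(self) -> dict:
        eligible = [r for r in self.rates if r.status != "excluded"]
        return {
            "n_groups": len(self.rates),
            "n_eligible": len(eligible),
            "n_contracting": len(self.contracting),
            "n_expanding": len(self.expanding),
            "lower_fence": self.lower_fence,
            "upper_fence": self.upper_fence,
        }


def distances_from_tree(tree, in_group: set[str] | list[str]) -> dict[str, float]:
    """Branch-length distance from the in-group LCA to each in-group tip.

    ``tree`` is a :class:`dendropy.Tree` or a path/Newick string.  Distances
    are sums of branch lengths along the path from the most recent common
    ancestor of ``in_group`` down to each tip.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(data=str(tree), schema="newick", rooting="force-rooted")
    tree.is_rooted = True
    in_group = list(in_group)
    labels = {t.label for t in tree.taxon_namespace}
    missing = [s for s in in_group if s not in labels]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("tree has a negative branch length")
    mrca = tree.mrca(taxon_labels=in_group)
    out: dict[str, float] = {}
    for leaf in mrca.leaf_iter():
        label = leaf.taxon.label
        if label not in in_group:
            continue
        d = 0.0
        node = leaf
        while node is not mrca:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[label] = d
    return out


def filter_groups(counts: CountMatrix) -> tuple[list[str], list[tuple[str, str]]]:
    """Partition groups into regression-eligible and excluded-with-reason.

    Eligible groups have a nonzero count in at least two species and
    non-identical counts across species.
    """
    mat = counts.counts.to_numpy()
    n_present = (mat > 0).sum(axis=1)
    identical = (mat == mat[:, [0]]).all(axis=1)
    eligible, excluded = [], []
    for gid, n_sp, same in zip(counts.group_ids, n_present, identical):
        if n_sp < 2:
            excluded.append((gid, "fewer_than_2_species"))
        elif same:
            excluded.append((gid, "identical_counts"))
        else:
            eligible.append(gid)
    return eligible, excluded


def ols_rate(
    group_counts: np.ndarray | pd.Series,
    distances: np.ndarray | dict[str, float],
    species: list[str] | None = None,
) -> tuple[float, float]:
    """OLS fit of copy number on distance-to-LCA: returns (slope, intercept).

    Accepts aligned arrays, or a species-keyed distance dict with ``species``
    naming the count order.  All species in the matrix contribute, including
    zero-count ones.
    """
    y = np.asarray(
        group_counts.to_numpy() if isinstance(group_counts, pd.Series) else group_counts,
        dtype=float,
    )
    if isinstance(distances, dict):
        if species is None:
            if not isinstance(group_counts, pd.Series):
                raise ValueError("species order required with a distance mapping")
            species = list(group_counts.index)
        x = np.array([distances[s] for s in species], dtype=float)
    else:
        x = np.asarray(distances, dtype=float)
    if x.shape != y.shape:
        raise ValueError("counts and distances must align")
    if np.unique(x).size < 2:
        raise ValueError("slope undefined: all distances equal")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def tukey_outliers(
    rates: dict[str, float] | pd.Series,
    multiplier: float = 1.5,
) -> dict:
    """Quartile (Tukey-fence) outlier analysis of rate values.

    Quartiles use linear interpolation (type 7, the numpy default); fences are
    ``Q1 - multiplier * IQR`` and ``Q3 + multiplier * IQR``.  Values strictly
    below the lower fence are contraction outliers, strictly above the upper
    fence expansion outliers.
    """
    s = pd.Series(rates, dtype=float)
    if len(s) < 4:
        raise ValueError("quartile analysis requires at least 4 values")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("rates must be finite")
    q1, q3 = np.percentile(s.to_numpy(), [25, 75])
    iqr = q3 - q1
    lower = q1 - multiplier * iqr
    upper = q3 + multiplier * iqr
    return {
        "lower_fence": float(lower),
        "upper_fence": float(upper),
        "outlier_low": set(s.index[s < lower]),
        "outlier_high": set(s.index[s > upper]),
    }


def classify_trends(
    counts: CountMatrix,
    distances: dict[str, float],
    multiplier: float = 1.5,
) -> TrendResult:
    """Full trend classification: filter, per-group OLS, fence outliers.

    Every group receives a :class:`GroupRate` whose status is ``excluded``
    (with reason), ``contracting`` (slope below the lower fence),
    ``expanding`` (above the upper fence) or ``neutral``.
    """
    missing = [s for s in counts.species if s not in distances]
    if missing:
        raise ValueError(f"no distance for species: {missing}")
    eligible, excluded = filter_groups(counts)
    x = np.array([distances[s] for s in counts.species], dtype=float)
    fits: dict[str, tuple[float, float]] = {}
    for gid in eligible:
        fits[gid] = ols_rate(counts.counts.loc[gid].to_numpy(), x)
    if len(fits) >= 4:
        fences = tukey_outliers({g: f[0] for g, f in fits.items()}, multiplier)
    else:
        fences = {
            "lower_fence": float("nan"),
            "upper_fence": float("nan"),
            "outlier_low": set(),
            "outlier_high": set(),
        }
    reasons = dict(excluded)
    rates = []
    for gid in counts.group_ids:
        if gid in reasons:
            rates.append(GroupRate(gid, float("nan"), float("nan"), "excluded", reasons[gid]))
            continue
        slope, intercept = fits[gid]
        if gid in fences["outlier_low"]:
            status = "contracting"
        elif gid in fences["outlier_high"]:
            status = "expanding"
        else:
            status = "neutral"
        rates.append(GroupRate(gid, slope, intercept, status))
    return TrendResult(rates, fences["lower_fence"], fences["upper_fence"])
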