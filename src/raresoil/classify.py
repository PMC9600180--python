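"""Abundance-category classification of OTUs and category-level flux.

OTUs are assigned, per soil system and from that soil's *initial* samples
only, to one of six occupancy-abundance categories defined by two relative
abundance cutoffs (0.01% for rarity, 1% for abundance):

========  ==========================================================
AAT       always abundant: >= 1% in every initial sample
CAT       conditionally abundant: >= 0.01% in every initial sample
          and >= 1% in at least one (but not all)
MT        moderate: within [0.01%, 1%) in every initial sample
CRT       conditionally rare: < 0.01% in at least one initial sample
          and never >= 1%
ART       always rare: < 0.01% in every initial sample
CRAT      conditionally rare and abundant: spans < 0.01% up to >= 1%
========  ==========================================================

OTUs absent from every initial sample of a soil but appearing later are
labelled ``NEW`` and treated as rare.  For two-way contrasts the categories
collapse to abundant = AAT + CAT, common = MT, rare = ART + CRT + NEW
(CRAT, should it occur, joins the rare side by default, configurably).

Boundary convention: a value exactly at the 0.01% cutoff counts as
moderate-side (the rarity test is strict ``<``), and a value exactly at 1%
counts as abundant-side (the abundance test is ``>=``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    InvalidConfigError,
    OtuTable,
    RelAbundanceTable,
    TableError,
    timepoint_order,
)

CATEGORIES = ("AAT", "CAT", "MT", "CRT", "ART", "CRAT", "NEW")
GROUPS = ("abundant", "common", "rare")


@dataclass
class Thresholds:
    """Relative-abundance cutoffs for rarity and abundance."""

    rare_cutoff: float = 1e-4
    abundant_cutoff: float = 1e-2

    def __post_init__(self) -> None:
        if not 0 < self.rare_cutoff < self.abundant_cutoff < 1:
            raise InvalidConfigError(
                "thresholds must satisfy 0 < rare_cutoff < abundant_cutoff < 1"
            )


@dataclass
class CategoryAssignment:
    """Per-OTU category labels for one soil system."""

    labels: pd.Series
    thresholds: Thresholds
    soil: str | None = None
    crat_group: str = "rare"

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(CATEGORIES)
        if bad:
            raise TableError(f"unknown category labels: {sorted(bad)}")

    def group_of(self, otu_ids=None) -> pd.Series:
        """Collapse categories to the abundant/common/rare grouping.

        OTU ids not present in the assignment are NEW by definition (they
        were absent from every initial sample) and grouped with rare.
        """
        mapping = {
            "AAT": "abundant",
            "CAT": "abundant",
            "MT": "common",
            "ART": "rare",
            "CRT": "rare",
            "NEW": "rare",
            "CRAT": self.crat_group,
        }
        if otu_ids is None:
            return self.labels.map(mapping)
        labels = self.labels.reindex(otu_ids).fillna("NEW")
        return labels.map(mapping)

    def counts(self) -> pd.Series:
        """Number of OTUs per category (Table-1 style bookkeeping)."""
        return self.labels.value_counts().reindex(CATEGORIES, fill_value=0)

    def write_tsv(self, path) -> None:
        out = self.labels.rename("category").to_frame()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")


class TaxaClassifier(BaseEstimator):
    """Classify OTUs into abundance categories from initial samples.

    scikit-learn style estimator: ``fit`` takes the OTUs x initial-samples
    relative-abundance matrix of one soil; ``predict`` labels any list of
    OTU ids, marking ids unseen at fit time as ``NEW``.

    The classification is scale-invariant: fitting on raw counts gives the
    same labels as fitting on proportions.
    """

    def __init__(
        self,
        rare_cutoff: float = 1e-4,
        abundant_cutoff: float = 1e-2,
        crat_group: str = "rare",
    ):
        self.rare_cutoff = rare_cutoff
        self.abundant_cutoff = abundant_cutoff
        self.crat_group = crat_group

    def fit(self, X, y=None):
        thr = Thresholds(self.rare_cutoff, self.abundant_cutoff)
        X = pd.DataFrame(X)
        p = X.div(X.sum(axis=0), axis=1).to_numpy()
        pmin = p.min(axis=1)
        pmax = p.max(axis=1)
        rc, ac = thr.rare_cutoff, thr.abundant_cutoff
        labels = np.where(
            pmin >= ac,
            "AAT",
            np.where(
                pmin >= rc,
                np.where(pmax >= ac, "CAT", "MT"),
                np.where(pmax >= ac, "CRAT", np.where(pmax < rc, "ART", "CRT")),
            ),
        )
        # an OTU never observed in any initial sample is not part of the
        # initial community at all: it is NEW, not always-rare
        labels = np.where(pmax == 0, "NEW", labels)
        self.labels_ = pd.Series(labels, index=X.index, name="category")
        self.thresholds_ = thr
        return self

    def predict(self, otu_ids) -> np.ndarray:
        return self.labels_.reindex(list(otu_ids)).fillna("NEW").to_numpy()

    def assignment(self, soil: str | None = None, all_otu_ids=None) -> CategoryAssignment:
        labels = self.labels_
        if all_otu_ids is not None:
            labels = labels.reindex(list(all_otu_ids)).fillna("NEW")
        return CategoryAssignment(
            labels, self.thresholds_, soil=soil, crat_group=self.crat_group
        )


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Convert counts to per-sample proportions (column-stochastic)."""
    sums = table.counts.sum(axis=0)
    zero = list(sums.index[sums == 0])
    if zero:
        raise TableError(f"all-zero samples cannot be normalized: {zero}")
    return RelAbundanceTable(table.counts.div(sums, axis=1), table.metadata.copy())


def classify_taxa(
    initial_rel: RelAbundanceTable,
    thresholds: Thresholds | None = None,
    crat_group: str = "rare",
) -> CategoryAssignment:
    """Classify the OTUs of one soil system from its initial samples."""
    thr = thresholds or Thresholds()
    md = initial_rel.metadata
    non_initial = list(md.index[md["timepoint"] != "initial"])
    if non_initial:
        raise TableError(f"non-initial samples present: {non_initial}")
    soils = md["soil"].unique()
    if len(soils) != 1:
        raise TableError(f"initial samples span multiple soils: {sorted(soils)}")
    clf = TaxaClassifier(thr.rare_cutoff, thr.abundant_cutoff, crat_group)
    clf.fit(initial_rel.proportions)
    return clf.assignment(soil=str(soils[0]))


@dataclass
class CategoryTimeseries:
    """Replicate-mean taxon-group shares over time, plus Sankey-style flows.

    ``shares`` is tidy with columns (soil, treatment, timepoint, group,
    share); the abundant/common/rare rows sum to 1 per timepoint, and an
    extra informational ``new`` row reports the invading-OTU share counted
    inside rare.  ``flows`` carries the per-group share change between
    consecutive timepoints.
    """

    shares: pd.DataFrame
    flows: pd.DataFrame = field(default_factory=pd.DataFrame)


def category_abundance_flux(
    rel: RelAbundanceTable, assignment: CategoryAssignment
) -> CategoryTimeseries:
    """Summed relative abundance of each taxon group per treatment and time."""
    missing = rel.proportions.index.difference(assignment.labels.index)
    if len(missing):
        raise TableError(f"OTUs without category assignment: {list(missing[:5])}")
    group = assignment.group_of(rel.proportions.index)
    is_new = assignment.labels.reindex(rel.proportions.index).eq("NEW").to_numpy()
    md = rel.metadata
    rows = []
    for (soil, tr, tp), samples in md.groupby(
        ["soil", "treatment", "timepoint"], sort=False
    ).groups.items():
        sub = rel.proportions[list(samples)]
        by_group = sub.groupby(group.to_numpy()).sum().mean(axis=1)
        for g in GROUPS:
            rows.append((soil, tr, tp, g, float(by_group.get(g, 0.0))))
        rows.append((soil, tr, tp, "new", float(sub.loc[is_new].sum(axis=0).mean())))
    shares = pd.DataFrame(
        rows, columns=["soil", "treatment", "timepoint", "group", "share"]
    )

    flow_rows = []
    for (soil, tr), block in shares[shares["group"] != "new"].groupby(
        ["soil", "treatment"], sort=False
    ):
        if tr == "none":
            continue
        # the initial node of every treatment's flow is the soil's initial state
        init = shares[
            (shares["soil"] == soil)
            & (shares["timepoint"] == "initial")
            & (shares["group"] != "new")
        ]
        seq = pd.concat([init.assign(treatment=tr), block])
        seq = seq.sort_values("timepoint", key=lambda s: s.map(timepoint_order))
        tps = seq["timepoint"].unique()
        for a, b in zip(tps[:-1], tps[1:]):
            fa = seq[seq["timepoint"] == a].set_index("group")["share"]
            fb = seq[seq["timepoint"] == b].set_index("group")["share"]
            for g in GROUPS:
                flow_rows.append(
                    (soil, tr, a, b, g, float(fa[g]), float(fb[g]), float(fb[g] - fa[g]))
                )
    flows = pd.DataFrame(
        flow_rows,
        columns=[
            "soil",
            "treatment",
            "from_timepoint",
            "to_timepoint",
            "group",
            "share_from",
            "share_to",
            "delta",
        ],
    )
    return CategoryTimeseries(shares, flows)
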