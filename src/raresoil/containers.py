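"""Core data containers and file I/O.

The package works on a single in-memory pair: an integer OTU count matrix
(OTUs x samples) and an aligned sample metadata table.  Samples follow the
mesocosm design of the study system: two soil microbiotas (``NCF``,
chemical-fertilizer field soil; ``NOF``, organic-fertilizer field soil),
five disturbance treatments (``AMB`` ambient, ``DR`` drought, ``FL``
flooding, ``FR`` freeze-thaw cycles, ``HE`` heat), five timepoints
(``initial`` plus recovery days ``R0``, ``R2``, ``R40``, ``R170``) and four
replicates per cell.

Tables are exchanged as plain tab-separated text (first column the OTU id,
header row the sample ids) and, optionally, as BIOM 1.0 JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOILS = ("NCF", "NOF")
TREATMENTS = ("AMB", "DR", "FL", "FR", "HE")
TIMEPOINTS = ("initial", "R0", "R2", "R40", "R170")
RECOVERY_TIMEPOINTS = ("R0", "R2", "R40", "R170")

#: Metadata columns every sample table must carry.
METADATA_COLUMNS = ("soil", "treatment", "timepoint", "replicate")


class RaresoilError(Exception):
    """Base class for errors raised by this package."""


class InvalidConfigError(RaresoilError, ValueError):
    """A configuration object violates its invariants."""


class TableError(RaresoilError, ValueError):
    """A count or proportion table violates its contract."""


def timepoint_order(tp: str) -> int:
    """Ordinal position of a timepoint label in the experimental sequence."""
    try:
        return TIMEPOINTS.index(tp)
    except ValueError as exc:
        raise TableError(f"unknown timepoint label {tp!r}") from exc


@dataclass
class OtuTable:
    """An integer OTU count matrix with aligned sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        OTUs x samples matrix of non-negative integer read counts.  The
        index holds unique OTU ids, the columns hold unique sample ids.
    metadata : pandas.DataFrame
        One row per sample (index = sample id) with at least the columns
        ``soil``, ``treatment``, ``timepoint`` and ``replicate``.  Initial
        samples carry ``treatment == "none"`` and ``timepoint == "initial"``.
    true_proportions : dict, optional
        Per-soil ground-truth relative abundances; populated only by the
        synthetic-community generator and used by its own consistency
        checks.  Absent for tables read from disk.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    true_proportions: dict[str, pd.Series] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate OTU ids: {dup[:5]}")
        if not self.counts.columns.is_unique:
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dup[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise TableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise TableError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise TableError(f"samples missing from metadata: {missing}")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing_cols:
            raise TableError(f"metadata lacks required columns: {missing_cols}")
        # keep metadata aligned to and ordered like the count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(
            self.counts[sample_ids].copy(),
            self.metadata.loc[sample_ids].copy(),
            true_proportions=self.true_proportions,
        )

    def subset_soil(self, soil: str) -> "OtuTable":
        keep = self.metadata.index[self.metadata["soil"] == soil]
        return self.subset_samples(keep)

    def initial_samples(self, soil: str | None = None) -> list[str]:
        md = self.metadata
        mask = md["timepoint"] == "initial"
        if soil is not None:
            mask &= md["soil"] == soil
        return list(md.index[mask])

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, counts_path, metadata_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            md = self.metadata.copy()
            md.index.name = "sample_id"
            md.to_csv(metadata_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path, metadata_path) -> "OtuTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        counts.index.name = None
        counts.columns.name = None
        metadata.index.name = None
        unmatched = [s for s in counts.columns if s not in metadata.index]
        if unmatched:
            raise TableError(f"samples missing from metadata: {unmatched}")
        return cls(counts, metadata)

    def write_biom(self, path) -> None:
        """Write the counts as a minimal BIOM 1.0 (JSON) document."""
        mat = self.counts.to_numpy()
        r, c = np.nonzero(mat)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "raresoil",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(mat.shape),
            "rows": [{"id": str(i), "metadata": None} for i in self.counts.index],
            "columns": [
                {"id": str(s), "metadata": self.metadata.loc[s].to_dict()}
                for s in self.counts.columns
            ],
            "data": [[int(i), int(j), int(mat[i, j])] for i, j in zip(r, c)],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def read_biom(cls, path) -> "OtuTable":
        """Read a BIOM 1.0 (JSON) OTU table with embedded sample metadata."""
        with open(path) as fh:
            doc = json.load(fh)
        shape = tuple(doc["shape"])
        otu_ids = [row["id"] for row in doc["rows"]]
        sample_ids = [col["id"] for col in doc["columns"]]
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type") == "dense":
            mat[:] = np.asarray(doc["data"], dtype=np.int64)
        else:
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = int(v)
        counts = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
        metadata = pd.DataFrame(
            [col.get("metadata") or {} for col in doc["columns"]], index=sample_ids
        )
        return cls(counts, metadata)


@dataclass
class RelAbundanceTable:
    """A column-stochastic relative-abundance matrix with aligned metadata."""

    proportions: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy()
        if (vals < 0).any():
            raise TableError("proportions must be non-negative")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [s for s, v in zip(self.proportions.columns, sums) if abs(v - 1) > 1e-9]
            raise TableError(f"columns do not sum to 1: {bad[:5]}")
        self.metadata = self.metadata.loc[list(self.proportions.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.proportions.columns)

    def subset_samples(self, sample_ids) -> "RelAbundanceTable":
        sample_ids = list(sample_ids)
        return RelAbundanceTable(
            self.proportions[sample_ids].copy(), self.metadata.loc[sample_ids].copy()
        )


def make_sample_id(soil: str, treatment: str, timepoint: str, replicate: int) -> str:
    """Canonical sample id: ``soil_treatment_timepoint_replicate``.

    Initial samples, which precede any treatment, use ``soil_initial_rep``.
    """
    if timepoint == "initial":
        return f"{soil}_initial_{replicate}"
    return f"{soil}_{treatment}_{timepoint}_{replicate}"
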