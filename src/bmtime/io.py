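"""Reading, writing, and filtering of count matrices, sample metadata, and gene sets.

Counts are stored probes-as-rows in a pandas DataFrame whose index holds probe
IDs following the targeted-panel convention ``GENE_probeid`` (gene symbol, an
underscore, then a numeric probe suffix); gene symbols are recovered by
splitting at the *last* underscore.  Two on-disk layouts are supported: plain
TSV (first column probe ID, header row of sample IDs) and Matrix Market
coordinate (.mtx) with ``<path>.rows`` / ``<path>.cols`` sidecar files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "compound", "concentration", "time_h",
                    "replicate", "is_vehicle"]


def probe_to_gene(probe: str) -> str:
    """Gene symbol of a probe ID: everything before the final underscore."""
    return probe.rsplit("_", 1)[0] if "_" in probe else probe


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.duplicated().any():
        raise ValueError("duplicate probe IDs in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in count matrix")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if np.any(arr < 0):
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix contains non-integer entries")
    return counts.astype(np.int64)


def read_counts(path) -> pd.DataFrame:
    """Read a probe x sample count matrix from TSV or Matrix Market layout."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        rows = Path(str(path) + ".rows").read_text().splitlines()
        cols = Path(str(path) + ".cols").read_text().splitlines()
        counts = pd.DataFrame(np.asarray(sparse.coo_matrix(mat).todense()),
                              index=rows, columns=cols)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
    counts.index.name = None
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    validate_counts(counts)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(counts.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(counts.index) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(counts.columns) + "\n")
    else:
        counts.to_csv(path, sep="\t", index_label="probe_id")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compound": str})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    md["is_vehicle"] = md["is_vehicle"].astype(bool)
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets (symbols) with optional per-set descriptions."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, 'name <tab> description <tab> members...'."""
    sets, desc = {}, {}
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {ln}: expected >= 3 tab-separated fields")
        name, description = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m)
        sets[name] = members
        desc[name] = description
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            d = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, d, *sorted(members)]) + "\n")


def select_samples(metadata: pd.DataFrame, compound: str,
                   time_points=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treated samples of one compound plus time-matched vehicle controls.

    Returns (treated, control) metadata subsets, each annotated with time and
    replicate.  Raises if the compound is unknown or a requested time point has
    no samples in either arm.
    """
    present = set(metadata.loc[~metadata["is_vehicle"], "compound"])
    if compound not in present:
        raise ValueError(f"compound {compound!r} not present in metadata")
    treated = metadata[(metadata["compound"] == compound) & (~metadata["is_vehicle"])]
    if time_points is not None:
        times = sorted(float(t) for t in time_points)
    else:
        times = sorted(treated["time_h"].unique())
    treated = treated[treated["time_h"].isin(times)]
    control = metadata[metadata["is_vehicle"] & metadata["time_h"].isin(times)]
    for t in times:
        if not (treated["time_h"] == t).any():
            raise ValueError(f"no treated samples at time {t} h")
        if not (control["time_h"] == t).any():
            raise ValueError(f"no vehicle samples at time {t} h")
    return treated.reset_index(drop=True), control.reset_index(drop=True)


def filter_low_counts(counts: pd.DataFrame, samples,
                      threshold: int = 100) -> pd.DataFrame:
    """Drop probes whose row sum over the selected samples is below ``threshold``.

    The comparison is inclusive (row sum >= threshold retains the probe); the
    filter is scoped per compound, i.e. ``samples`` should be that compound's
    treated plus control columns.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample selection")
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing[:5]}")
    keep = counts[samples].sum(axis=1) >= threshold
    out = counts.loc[keep]
    logger.info("low-count filter: %d of %d probes retained (threshold %s)",
                out.shape[0], counts.shape[0], threshold)
    return out
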