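"""Count-matrix and experimental-design data model with tab-separated I/O.

The central object is a plain :class:`pandas.DataFrame` of non-negative
integer read counts with genes as rows (index = gene identifiers) and
samples as columns.  A :class:`Design` maps each sample to its experimental
condition and knows the replicate count of every condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountDataError",
    "Design",
    "read_count_table",
    "write_count_table",
    "validate_count_table",
    "validate_design",
]


class CountDataError(ValueError):
    """Raised for malformed count tables or designs."""


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a count table and return it with integer dtype.

    Requires unique gene identifiers, unique sample names, and non-negative
    integer entries.  Raises :class:`CountDataError` naming the offending
    cell otherwise.
    """
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise CountDataError(f"duplicate gene ID: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise CountDataError(f"duplicate sample name: {dup!r}")
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~counts.isna()
    bad |= counts.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise CountDataError(
            f"non-numeric count at gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {counts.iat[i, j]!r}"
        )
    arr = numeric.to_numpy()
    nonint = arr != np.floor(arr)
    if nonint.any():
        i, j = np.argwhere(nonint)[0]
        raise CountDataError(
            f"non-integer count at gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {arr[i, j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise CountDataError(
            f"negative count at gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {arr[i, j]!r}"
        )
    out = numeric.astype(np.int64)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def read_count_table(path) -> pd.DataFrame:
    """Read a tab-separated count table.

    Expected layout: first row is a header of sample names (first cell,
    conventionally ``gene_id``, is ignored), first column holds gene IDs,
    remaining cells are non-negative integer counts.  UTF-8, no quoting.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise CountDataError(f"duplicate sample name: {dup!r}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          quoting=3, comment=None)
    except Exception as exc:  # malformed TSV structure
        raise CountDataError(f"cannot parse count table {path}: {exc}") from exc
    raw.columns = header
    raw.index.name = None
    return validate_count_table(raw)


def write_count_table(counts: pd.DataFrame, path, id_header: str = "gene_id") -> None:
    """Write a count table in the tab-separated layout read by
    :func:`read_count_table` (integer-exact round trip)."""
    counts.to_csv(path, sep="\t", index_label=id_header)


@dataclass
class Design:
    """Assignment of samples to experimental conditions.

    Parameters
    ----------
    condition_of_sample
        Mapping sample name -> condition label.
    """

    condition_of_sample: dict[str, str]
    replicate_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._recount()

    def _recount(self) -> None:
        counts: dict[str, int] = {}
        for cond in self.condition_of_sample.values():
            counts[cond] = counts.get(cond, 0) + 1
        self.replicate_count = counts

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond in self.condition_of_sample.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of_sample.items() if c == condition]

    @classmethod
    def from_labels(cls, samples, labels) -> "Design":
        if len(samples) != len(labels):
            raise CountDataError("sample and label lists differ in length")
        return cls(dict(zip(map(str, samples), map(str, labels))))

    @classmethod
    def from_tsv(cls, path) -> "Design":
        """Read a two-column (sample, condition) tab-separated file.

        A header line is optional; it is detected by the conventional
        column names ``sample``/``condition`` in the first row.
        """
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, quoting=3)
        if df.shape[1] < 2:
            raise CountDataError("design file needs two tab-separated columns")
        first = [str(x).lower() for x in df.iloc[0, :2]]
        if first[0] in ("sample", "sample_name") or first[1] in ("condition", "group"):
            df = df.iloc[1:]
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        if len(mapping) != len(df):
            raise CountDataError("duplicate sample name in design file")
        return cls(mapping)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.condition_of_sample),
             "condition": list(self.condition_of_sample.values())}
        ).to_csv(path, sep="\t", index=False)


def validate_design(counts: pd.DataFrame, design: Design) -> Design:
    """Check that the design labels exactly the samples of ``counts``.

    Returns the design with ``replicate_count`` (re)populated.  Idempotent.
    """
    table_samples = set(map(str, counts.columns))
    design_samples = set(design.condition_of_sample)
    missing = sorted(table_samples - design_samples)
    if missing:
        raise CountDataError(f"sample {missing[0]!r} has no condition label")
    unknown = sorted(design_samples - table_samples)
    if unknown:
        raise CountDataError(f"design references unknown sample {unknown[0]!r}")
    design._recount()
    return design
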