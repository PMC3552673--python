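"""Tabular I/O for the pipeline and the present-call filter.

The pipeline consumes MAS5-style summaries, never raw array files: a signal
matrix (probes x samples), a matching detection-call matrix (P/A/M), a sample
design sheet (exposure duration in days, Cd2+ dose in uM), a probe annotation
table, and gene sets in GMT format.  All files are plain UTF-8 TSV/CSV with
headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_CALLS = frozenset({"P", "A", "M"})

__all__ = [
    "ExpressionStudy",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "filter_present",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "collapse_probes",
]


@dataclass
class ExpressionStudy:
    """A probes x samples expression study with detection calls and design.

    Attributes
    ----------
    signal : DataFrame
        Non-negative expression values, index = probe ids, columns = sample
        ids (order defines the analysis order).
    calls : DataFrame
        Detection calls in {P, A, M}, same shape/labels as ``signal``.
    design : DataFrame
        One row per sample (index = sample id, aligned with the signal
        columns) with columns ``time_days`` and ``dose_uM``.
    """

    signal: pd.DataFrame
    calls: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.signal.shape != self.calls.shape:
            raise ValueError(
                f"signal is {self.signal.shape} but calls is {self.calls.shape}"
            )
        if list(self.signal.index) != list(self.calls.index):
            raise ValueError("signal and calls disagree on probe ids/order")
        if list(self.signal.columns) != list(self.calls.columns):
            raise ValueError("signal and calls disagree on sample ids/order")
        if self.design.index.has_duplicates:
            dup = self.design.index[self.design.index.duplicated()][0]
            raise ValueError(f"sample {dup!r} appears more than once in design")
        missing = [s for s in self.signal.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        extra = [s for s in self.design.index if s not in self.signal.columns]
        if extra:
            raise ValueError(f"unknown sample in design: {extra}")
        # keep design aligned with matrix column order
        self.design = self.design.loc[list(self.signal.columns)]
        for col in ("time_days", "dose_uM"):
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
        if (self.design["dose_uM"] < 0).any():
            bad = self.design.index[self.design["dose_uM"] < 0][0]
            raise ValueError(f"negative dose for sample {bad!r}")
        values = self.signal.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            for col in self.signal.columns:
                coerced = pd.to_numeric(self.signal[col], errors="coerce")
                if coerced.isna().any():
                    row = self.signal.index[coerced.isna()][0]
                    raise ValueError(
                        f"non-numeric signal at probe {row!r}, sample {col!r}"
                    )
            values = self.signal.to_numpy()
        if not all(dt == np.float64 for dt in self.signal.dtypes):
            self.signal = self.signal.astype(float)
            values = self.signal.to_numpy()
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing signal at probe {self.signal.index[i]!r}, "
                f"sample {self.signal.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative signal at probe {self.signal.index[i]!r}, "
                f"sample {self.signal.columns[j]!r}"
            )
        bad_calls = ~self.calls.isin(VALID_CALLS)
        if bad_calls.to_numpy().any():
            i, j = np.argwhere(bad_calls.to_numpy())[0]
            raise ValueError(
                f"call {self.calls.iat[i, j]!r} outside {{P,A,M}} at probe "
                f"{self.calls.index[i]!r}, sample {self.calls.columns[j]!r}"
            )

    @property
    def probes(self) -> list[str]:
        return list(self.signal.index)

    @property
    def samples(self) -> list[str]:
        return list(self.signal.columns)

    def block(self, time_days: float) -> "ExpressionStudy":
        """Restrict to the samples of one exposure block (1 or 13 days)."""
        keep = self.design.index[self.design["time_days"] == time_days]
        if len(keep) == 0:
            raise ValueError(f"no samples with time_days == {time_days}")
        return ExpressionStudy(
            signal=self.signal[list(keep)].copy(),
            calls=self.calls[list(keep)].copy(),
            design=self.design.loc[list(keep)].copy(),
        )


def read_expression(matrix_path, calls_path, design_path) -> ExpressionStudy:
    """Load a study from a signal TSV, a calls TSV and a design CSV.

    Column order is taken from the matrix file; the design rows are reordered
    to match.  Any dimension mismatch, unknown sample, non-numeric signal or
    invalid call symbol is rejected with the offending row/column named.
    """
    signal = pd.read_csv(matrix_path, sep="\t", index_col=0)
    calls = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
    design = pd.read_csv(design_path, index_col="sample_id")
    return ExpressionStudy(signal=signal, calls=calls, design=design)


def write_expression(study: ExpressionStudy, matrix_path, calls_path, design_path) -> None:
    """Write the three study files; full float precision (round-trip safe)."""
    study.signal.rename_axis("probe").to_csv(matrix_path, sep="\t", float_format="%.17g")
    study.calls.rename_axis("probe").to_csv(calls_path, sep="\t")
    study.design.rename_axis("sample_id").to_csv(design_path)


def filter_present(study: ExpressionStudy) -> ExpressionStudy:
    """Keep the probes detected Present in at least one sample.

    This defines the analysis universe; Marginal counts as not-Present.
    Idempotent, order preserving, and an empty result is allowed.
    """
    mask = (study.calls == "P").any(axis=1)
    return ExpressionStudy(
        signal=study.signal.loc[mask].copy(),
        calls=study.calls.loc[mask].copy(),
        design=study.design.copy(),
    )


# ---------------------------------------------------------------------------
# probe annotation


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV (columns: probe, symbol, gene_name).

    NA symbols are kept as missing values; one row per probe is enforced.
    """
    ann = pd.read_csv(path, sep="\t", index_col="probe", dtype=str)
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"probe {dup!r} annotated more than once")
    for col in ("symbol", "gene_name"):
        if col not in ann.columns:
            raise ValueError(f"annotation lacks required column {col!r}")
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.rename_axis("probe").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member symbols)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>symbols...``.

    Duplicate symbols within a line are dropped (first occurrence kept);
    a line with fewer than 3 fields is rejected with its line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name, desc, *symbols = fields
            seen: dict[str, None] = {}
            for s in symbols:
                if s and s not in seen:
                    seen[s] = None
            if not seen:
                raise ValueError(f"{path}: line {lineno} ({name!r}) has no genes")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = (desc, list(seen))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, symbols) in collection:
            fh.write("\t".join([name, desc, *symbols]) + "\n")


# ---------------------------------------------------------------------------
# probe -> gene collapsing

COLLAPSE_RULES = ("min_p", "max_abs_t")


def collapse_probes(
    results: pd.DataFrame,
    annotation: pd.DataFrame | Mapping[str, str],
    rule: str = "min_p",
) -> pd.DataFrame:
    """Collapse a per-probe result table to one row per gene symbol.

    Parameters
    ----------
    results : DataFrame
        Per-probe statistics indexed by probe id; must carry a ``p`` column
        for rule ``min_p`` or a ``t`` column for rule ``max_abs_t``.
    annotation : DataFrame or mapping
        probe -> symbol (NA symbols excluded from the gene-level table).
    rule : str
        ``min_p`` keeps the probe with the smallest P value per gene;
        ``max_abs_t`` the probe with the largest |t|.

    Returns
    -------
    DataFrame indexed by symbol, carrying the representative probe's full row
    plus a ``probe`` column naming it.
    """
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {rule!r}; choose from {COLLAPSE_RULES}")
    if isinstance(annotation, pd.DataFrame):
        symbol_of = annotation["symbol"]
    else:
        symbol_of = pd.Series(dict(annotation))
    tab = results.copy()
    tab["symbol"] = tab.index.map(symbol_of)
    tab = tab[tab["symbol"].notna()]
    if rule == "min_p":
        key = tab["p"].to_numpy()
    else:
        key = -tab["t"].abs().to_numpy()
    tab = tab.assign(_key=key)
    # stable: ties resolved by probe order in the input table
    best = tab.sort_values("_key", kind="stable").groupby("symbol", sort=True).head(1)
    best = best.drop(columns="_key").rename_axis("probe").reset_index()
    return best.set_index("symbol").sort_index()
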