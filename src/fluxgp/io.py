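"""Long-format multi-output time-course container and delimited-text I/O.

Observation tables are long-format with columns ``output``, ``time``,
``value`` — one row per measurement — which naturally supports outputs that
are sampled at different (and different numbers of) time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesSet", "ParseError", "read_timeseries", "write_timeseries"]

REQUIRED_COLUMNS = ("output", "time", "value")


class ParseError(ValueError):
    """A delimited observation table failed validation."""


@dataclass
class TimeSeriesSet:
    """Observed multi-output time-course data.

    Wraps a long-format :class:`pandas.DataFrame` with columns
    ``output`` (label), ``time`` (float) and ``value`` (float).  Duplicate
    ``(output, time)`` pairs are rejected unless ``allow_replicates`` is set
    (replicated measurements at the same time are legitimate data but must be
    opted into).
    """

    frame: pd.DataFrame
    allow_replicates: bool = False

    def __post_init__(self):
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["output"] = df["output"].astype(str)
        for col in ("time", "value"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()].tolist()
            if bad:
                raise ParseError(f"non-numeric {col!r} entries at rows {bad[:10]}")
            df[col] = vals
        if df["time"].isna().any() or df["value"].isna().any():
            bad = df.index[df[["time", "value"]].isna().any(axis=1)].tolist()
            raise ParseError(f"missing time/value entries at rows {bad[:10]}")
        if not np.all(np.isfinite(df["time"].to_numpy())):
            raise ParseError("non-finite times")
        if not self.allow_replicates:
            dup = df.duplicated(subset=["output", "time"])
            if dup.any():
                rows = df.index[dup].tolist()
                raise ParseError(
                    f"duplicate (output, time) pairs at rows {rows[:10]}; "
                    "pass allow_replicates=True if these are true replicates"
                )
        if len(df) == 0:
            raise ParseError("empty observation table")
        self.frame = df.reset_index(drop=True)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, tuple[Sequence[float], Sequence[float]]],
                    allow_replicates: bool = False) -> "TimeSeriesSet":
        """Build from ``{output: (times, values)}``."""
        rows = []
        for o, (t, v) in arrays.items():
            t = np.asarray(t, float)
            v = np.asarray(v, float)
            if t.shape != v.shape:
                raise ParseError(f"times/values length mismatch for output {o!r}")
            rows.append(pd.DataFrame({"output": o, "time": t, "value": v}))
        return cls(pd.concat(rows, ignore_index=True), allow_replicates=allow_replicates)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, float, float]],
                     allow_replicates: bool = False) -> "TimeSeriesSet":
        df = pd.DataFrame(list(records), columns=list(REQUIRED_COLUMNS))
        return cls(df, allow_replicates=allow_replicates)

    # -- accessors -----------------------------------------------------------

    @property
    def outputs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for o in self.frame["output"]:
            seen.setdefault(o, None)
        return tuple(seen)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def counts(self) -> dict[str, int]:
        return {o: int((self.frame["output"] == o).sum()) for o in self.outputs}

    def times(self, output: str) -> np.ndarray:
        sel = self.frame.loc[self.frame["output"] == output, "time"]
        if sel.empty:
            raise KeyError(f"no observations for output {output!r}")
        return sel.to_numpy(float)

    def values(self, output: str) -> np.ndarray:
        sel = self.frame.loc[self.frame["output"] == output, "value"]
        if sel.empty:
            raise KeyError(f"no observations for output {output!r}")
        return sel.to_numpy(float)

    def subset(self, outputs: Sequence[str]) -> "TimeSeriesSet":
        df = self.frame[self.frame["output"].isin(list(outputs))]
        return TimeSeriesSet(df.copy(), allow_replicates=self.allow_replicates)

    def centered(self) -> tuple["TimeSeriesSet", dict[str, float]]:
        """Per-output mean-centred copy, plus the removed means."""
        means = {o: float(np.mean(self.values(o))) for o in self.outputs}
        df = self.frame.copy()
        df["value"] = df["value"] - df["output"].map(means)
        return TimeSeriesSet(df, allow_replicates=self.allow_replicates), means

    def validate_for_fit(self, min_points: int = 3) -> None:
        """Require at least ``min_points`` observations per output before fitting."""
        low = {o: n for o, n in self.counts().items() if n < min_points}
        if low:
            raise ParseError(
                f"outputs with fewer than {min_points} observations: {low}"
            )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def read_timeseries(path: str | Path, dialect: str | None = None,
                    allow_replicates: bool = False) -> TimeSeriesSet:
    """Read a long-format observation table from delimited text.

    ``dialect`` is ``"comma"``, ``"tab"`` or ``None`` (inferred from the file
    extension, ``.tsv`` meaning tab).  Error messages carry 1-based file line
    numbers (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    if dialect is None:
        dialect = "tab" if path.suffix.lower() in {".tsv", ".tab"} else "comma"
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no parseable rows") from exc
    if len(df) == 0:
        raise ParseError(f"{path}: table has a header but no data rows")
    try:
        return TimeSeriesSet(df, allow_replicates=allow_replicates)
    except ParseError as exc:
        raise _with_line_numbers(path, df, exc) from exc


def _with_line_numbers(path: Path, df: pd.DataFrame, exc: ParseError) -> ParseError:
    """Translate dataframe row indices in a message to file line numbers."""
    msg = str(exc)
    import re

    def repl(m):
        rows = [int(r) for r in re.findall(r"\d+", m.group(0))]
        lines = [r + 2 for r in rows]  # +1 header, +1 zero-based
        return f"file lines {lines}"

    msg = re.sub(r"rows \[[^\]]*\]", repl, msg)
    return ParseError(f"{path}: {msg}")


def write_timeseries(ts: TimeSeriesSet, path: str | Path, dialect: str = "comma") -> None:
    sep = {"comma": ",", "tab": "\t"}[dialect]
    ts.to_csv(path, sep=sep)
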