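"""Measurement-table container and delimited-text I/O.

A measurement table holds strictly positive linear measurements (µm) for a
set of specimens, together with an OTU label and a sex label per specimen.
Rows with missing or nonpositive entries are dropped with a warning rather
than imputed.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default character set: 16 linear measurements used throughout.
DEFAULT_CHARACTERS: tuple[str, ...] = (
    "cly.b", "eye.d", "eye.h", "flgfirst.l", "flglast.b", "flglast.l",
    "hea.b", "hea.h", "lof.l", "msp.l", "ool.l", "pol.l",
    "scp.b", "scp.l", "tib3.b", "tib3.l",
)

VALID_SEXES = frozenset({"female", "male"})

_META_COLUMNS = ("specimen_id", "otu", "sex")


class TableValidationError(ValueError):
    """Raised when a measurement table violates its invariants."""


@dataclass(frozen=True)
class MeasurementTable:
    """Labeled positive measurement matrix (specimens x characters).

    Attributes
    ----------
    specimen_id : array of unique specimen labels, length n.
    otu : array of OTU labels, length n.
    sex : array with entries in ``{"female", "male"}``, length n.
    characters : ordered character names, length p (p >= 2).
    values : (n, p) float array, strictly positive, in µm.
    """

    specimen_id: np.ndarray
    otu: np.ndarray
    sex: np.ndarray
    characters: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.specimen_id)
        if len(self.otu) != n or len(self.sex) != n:
            raise TableValidationError("label arrays must share one length")
        if self.values.shape != (n, len(self.characters)):
            raise TableValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} specimens x {len(self.characters)} characters"
            )
        if len(self.characters) < 2:
            raise TableValidationError("need at least 2 characters")
        if len(set(self.specimen_id)) != n:
            dupes = pd.Series(self.specimen_id).value_counts()
            dupes = sorted(dupes[dupes > 1].index)
            raise TableValidationError(f"duplicate specimen ids: {dupes}")
        bad_sex = set(self.sex) - VALID_SEXES
        if bad_sex:
            raise TableValidationError(f"invalid sex labels: {sorted(bad_sex)}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            bad = np.argwhere(~(np.isfinite(self.values) & (self.values > 0)))
            i, j = bad[0]
            raise TableValidationError(
                f"nonpositive/missing value for specimen "
                f"{self.specimen_id[i]!r}, character {self.characters[j]!r}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, characters: tuple[str, ...] | None = None,
        drop_invalid: bool = True,
    ) -> "MeasurementTable":
        """Build a table from a dataframe with specimen_id/otu/sex columns.

        All remaining columns (or ``characters`` if given) are measurement
        characters. When ``drop_invalid`` is set, rows containing missing or
        nonpositive measurements are dropped with a logged warning.
        """
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"missing required columns: {missing}")
        if characters is None:
            characters = tuple(c for c in df.columns if c not in _META_COLUMNS)
        vals = df.loc[:, list(characters)].apply(pd.to_numeric, errors="coerce")
        ok = np.isfinite(vals.to_numpy(float)).all(axis=1) & (
            vals.to_numpy(float) > 0
        ).all(axis=1, where=np.isfinite(vals.to_numpy(float)))
        if not ok.all():
            dropped = df.loc[~ok, "specimen_id"].tolist()
            if not drop_invalid:
                raise TableValidationError(
                    f"rows with missing/nonpositive measurements: {dropped}"
                )
            logger.warning(
                "dropping %d specimen(s) with missing or nonpositive "
                "measurements: %s", len(dropped), dropped,
            )
            warnings.warn(
                f"dropped {len(dropped)} specimen(s) with invalid measurements",
                stacklevel=2,
            )
        df = df.loc[ok]
        return cls(
            specimen_id=df["specimen_id"].astype(str).to_numpy(),
            otu=df["otu"].astype(str).to_numpy(),
            sex=df["sex"].astype(str).str.lower().to_numpy(),
            characters=tuple(characters),
            values=vals.loc[ok].to_numpy(float),
        )

    # -- views -------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.specimen_id)

    @property
    def p(self) -> int:
        return len(self.characters)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.characters))
        df.insert(0, "sex", self.sex)
        df.insert(0, "otu", self.otu)
        df.insert(0, "specimen_id", self.specimen_id)
        return df

    def select(self, mask: np.ndarray) -> "MeasurementTable":
        return MeasurementTable(
            self.specimen_id[mask], self.otu[mask], self.sex[mask],
            self.characters, self.values[mask],
        )

    def by_sex(self, sex: str) -> "MeasurementTable":
        if sex not in VALID_SEXES:
            raise TableValidationError(f"unknown sex {sex!r}")
        return self.select(self.sex == sex)

    def by_otu(self, *otus: str) -> "MeasurementTable":
        return self.select(np.isin(self.otu, list(otus)))

    def single_sex(self) -> str:
        """Return the unique sex label, or raise if sexes are mixed."""
        sexes = sorted(set(self.sex))
        if len(sexes) != 1:
            raise TableValidationError(
                "table mixes sexes; analyze sexes separately or pass an "
                "explicit override"
            )
        return sexes[0]


def read_measurements(
    path: str | Path, characters: tuple[str, ...] | None = None,
) -> MeasurementTable:
    """Read a delimited measurement table (comma or tab, auto-detected).

    Header must contain specimen_id, otu, sex followed by character columns;
    values are in µm.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise TableValidationError(f"{path}: empty file")
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    return MeasurementTable.from_dataframe(df, characters=characters)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a table as CSV (byte-stable float formatting)."""
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")


def load_reference_moments() -> pd.DataFrame:
    """Bundled per-group measurement summaries (min/max/mean/SD, µm).

    Used to calibrate the synthetic morphometric generator to a realistic
    five-species social-wasp dataset.
    """
    path = Path(__file__).parent / "data" / "gallicus_group_moments.tsv"
    return pd.read_csv(path, sep="\t")
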