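"""SBS-96 data model and COSMIC-dialect TSV readers/writers.

Single-base-substitution catalogues classify each somatic mutation into one
of 96 channels: 6 pyrimidine-centred substitution types (C>A, C>G, C>T, T>A,
T>C, T>G) times 16 flanking trinucleotide contexts.  All objects in this
package share one canonical, substitution-major channel order; files whose
rows arrive in any other order are re-sorted on load.

The on-disk dialect matches COSMIC v3 signature files: UTF-8 TSV, a first
column ``MutationType`` holding labels such as ``A[C>A]A``, and one column
per sample (catalogues) or per signature (profile matrices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SBSCatalogue",
    "SignatureMatrix",
    "ExposureMatrix",
    "SBSFormatError",
    "SBSValidationError",
    "canonical_channels",
    "read_catalogue",
    "write_catalogue",
    "read_signatures",
    "write_signatures",
    "read_exposures",
    "write_exposures",
]

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"


class SBSFormatError(ValueError):
    """A file does not conform to the SBS-96 TSV dialect."""


class SBSValidationError(ValueError):
    """Data violate an SBS-96 object invariant (e.g. negative counts)."""


def canonical_channels() -> list[str]:
    """Return the 96 channel labels in canonical substitution-major order.

    Order: substitution types C>A, C>G, C>T, T>A, T>C, T>G; within each,
    the 5' base cycles A,C,G,T slowest and the 3' base fastest, giving
    ``A[C>A]A, A[C>A]C, ..., T[T>G]T``.
    """
    return [
        f"{five}[{sub}]{three}"
        for sub, five, three in itertools.product(_SUBSTITUTIONS, _BASES, _BASES)
    ]


_CANONICAL = canonical_channels()
_CANONICAL_SET = frozenset(_CANONICAL)
_CANONICAL_INDEX = {c: i for i, c in enumerate(_CANONICAL)}


@dataclass
class SBSCatalogue:
    """A samples x 96 matrix of non-negative integer mutation counts.

    Attributes
    ----------
    counts : ndarray of shape (m, 96)
        Integer mutation counts per sample and channel.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    channels : list of str
        Always the canonical 96-label order.
    """

    counts: np.ndarray
    sample_ids: list[str]
    channels: list[str] = field(default_factory=canonical_channels)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise SBSValidationError(
                f"counts must be m x 96, got shape {self.counts.shape}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int, atol=1e-9, rtol=0):
                bad = np.argwhere(np.abs(self.counts - as_int) > 1e-9)[0]
                raise SBSValidationError(
                    f"non-integer count at sample {bad[0]}, channel {bad[1]}: "
                    f"{self.counts[bad[0], bad[1]]!r}"
                )
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise SBSValidationError(
                f"negative count at sample {bad[0]}, channel {bad[1]}: "
                f"{self.counts[bad[0], bad[1]]}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.counts.shape[0]:
            raise SBSValidationError(
                f"{len(self.sample_ids)} sample ids for {self.counts.shape[0]} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SBSValidationError(f"duplicate sample ids: {dupes}")
        if list(self.channels) != _CANONICAL:
            raise SBSValidationError("channels must be in canonical order")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total mutation burden N_g."""
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-sample channel frequencies p_g = counts_g / N_g.

        Rows with zero burden are returned as all-zero rather than NaN.
        """
        totals = self.totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / totals[:, None]
        p[totals == 0] = 0.0
        return p

    def to_frame(self) -> pd.DataFrame:
        """COSMIC-layout DataFrame: channels as rows, samples as columns."""
        return pd.DataFrame(
            self.counts.T, index=pd.Index(self.channels, name="MutationType"),
            columns=self.sample_ids,
        )


@dataclass
class SignatureMatrix:
    """A 96 x k matrix of signature profiles (columns).

    ``normalized`` is True when every column sums to 1, i.e. each profile is
    a probability distribution over the 96 channels.
    """

    profiles: np.ndarray
    signature_ids: list[str]
    channels: list[str] = field(default_factory=canonical_channels)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != 96:
            raise SBSValidationError(
                f"profiles must be 96 x k, got shape {self.profiles.shape}"
            )
        if self.profiles.shape[1] < 1:
            raise SBSValidationError("need at least one signature column")
        if (self.profiles < 0).any():
            raise SBSValidationError("signature profiles must be non-negative")
        self.signature_ids = [str(s) for s in self.signature_ids]
        if len(self.signature_ids) != self.profiles.shape[1]:
            raise SBSValidationError("signature_ids do not match column count")
        if list(self.channels) != _CANONICAL:
            raise SBSValidationError("channels must be in canonical order")

    @property
    def k(self) -> int:
        return self.profiles.shape[1]

    @property
    def normalized(self) -> bool:
        return bool(np.allclose(self.profiles.sum(axis=0), 1.0, atol=1e-9))

    def normalize(self) -> "SignatureMatrix":
        """Return a copy with each column scaled to sum to 1."""
        sums = self.profiles.sum(axis=0)
        if (sums <= 0).any():
            bad = [self.signature_ids[i] for i in np.flatnonzero(sums <= 0)]
            raise SBSValidationError(f"cannot normalize zero-sum column(s): {bad}")
        return SignatureMatrix(self.profiles / sums, list(self.signature_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=pd.Index(self.channels, name="MutationType"),
            columns=self.signature_ids,
        )


@dataclass
class ExposureMatrix:
    """A samples x k matrix of non-negative signature attributions."""

    values: np.ndarray
    sample_ids: list[str]
    signature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SBSValidationError("exposures must be a 2-D matrix")
        if (self.values < 0).any():
            raise SBSValidationError("exposures must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.signature_ids = [str(s) for s in self.signature_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise SBSValidationError("sample_ids do not match row count")
        if len(self.signature_ids) != self.values.shape[1]:
            raise SBSValidationError("signature_ids do not match column count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="Sample"),
            columns=self.signature_ids,
        )


# ---------------------------------------------------------------------------
# TSV input / output


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def _channel_axis(frame: pd.DataFrame) -> Literal["rows", "columns"]:
    """Decide which axis of a table holds the 96 channels.

    An axis qualifies when at least 90 of its labels are canonical channel
    labels; requiring a large majority tolerates stray annotation rows while
    still catching transposed files.  Both axes qualifying is ambiguous.
    """
    rows = sum(1 for c in frame.index.astype(str) if c in _CANONICAL_SET)
    cols = sum(1 for c in frame.columns.astype(str) if c in _CANONICAL_SET)
    if rows >= 90 and cols >= 90:
        raise SBSFormatError("both axes look like SBS-96 channels; cannot orient")
    if rows >= 90:
        return "rows"
    if cols >= 90:
        return "columns"
    raise SBSFormatError(
        "neither axis matches the 96 canonical SBS channel labels "
        f"(rows matched {rows}, columns matched {cols})"
    )


def _validate_channel_index(labels: Sequence[str]) -> np.ndarray:
    """Map file channel labels to canonical positions, validating the set."""
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    dupes = sorted({x for x in labels if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
    if dupes:
        raise SBSFormatError(f"duplicate channel label(s): {dupes}")
    unknown = sorted(set(labels) - _CANONICAL_SET)
    if unknown:
        raise SBSFormatError(f"unknown channel label(s): {unknown[:5]}")
    missing = sorted(_CANONICAL_SET - set(labels))
    if missing:
        raise SBSFormatError(
            f"missing {len(missing)} channel label(s), e.g. {missing[:5]}"
        )
    return np.array([_CANONICAL_INDEX[x] for x in labels])


def _channels_as_rows(frame: pd.DataFrame, orientation: str) -> pd.DataFrame:
    if orientation == "auto":
        axis = _channel_axis(frame)
    elif orientation == "samples_as_columns":
        axis = "rows"
    elif orientation == "samples_as_rows":
        axis = "columns"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if axis == "columns":
        frame = frame.T
    order = _validate_channel_index(frame.index)
    out = frame.iloc[np.argsort(order)]
    out.index = _CANONICAL
    return out


def read_catalogue(
    path: str | Path,
    orientation: Literal["auto", "samples_as_columns", "samples_as_rows"] = "auto",
    round_counts: bool = False,
) -> SBSCatalogue:
    """Read an SBS-96 mutation catalogue from a COSMIC-dialect TSV.

    Parameters
    ----------
    path
        TSV with a header row; one axis must carry the 96 canonical channel
        labels (any row order; re-sorted on load).
    orientation
        ``auto`` detects which axis holds the channels; the explicit values
        force an interpretation.
    round_counts
        When True, near-integer float counts are rounded instead of
        rejected.  Counts are rejected by default because the Poisson /
        multinomial semantics of the model require integers.
    """
    frame = _channels_as_rows(_read_table(path), orientation)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise SBSFormatError(f"non-numeric values in catalogue {path}")
    counts = values.T  # samples x 96
    if round_counts:
        counts = np.rint(counts)
    else:
        rounded = np.rint(counts)
        if not np.array_equal(counts, rounded):
            s, c = np.argwhere(counts != rounded)[0]
            raise SBSValidationError(
                f"non-integer count at sample {frame.columns[s]!r}, "
                f"channel {_CANONICAL[c]!r}: {counts[s, c]} "
                "(pass round_counts=True to round)"
            )
    return SBSCatalogue(counts, list(frame.columns.astype(str)))


def write_catalogue(catalogue: SBSCatalogue, path: str | Path) -> None:
    """Write a catalogue as COSMIC-layout TSV (channels as rows, integers)."""
    catalogue.to_frame().to_csv(path, sep="\t")


def read_signatures(path: str | Path, orientation: str = "auto") -> SignatureMatrix:
    """Read a 96 x k signature matrix from a COSMIC/Signal-style TSV."""
    frame = _channels_as_rows(_read_table(path), orientation)
    return SignatureMatrix(frame.to_numpy(dtype=float), list(frame.columns.astype(str)))


def write_signatures(signatures: SignatureMatrix, path: str | Path) -> None:
    """Write signatures as TSV, 96 rows in canonical order, full precision."""
    signatures.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_exposures(path: str | Path) -> ExposureMatrix:
    """Read an exposure matrix (samples as rows, signatures as columns)."""
    frame = _read_table(path)
    return ExposureMatrix(
        frame.to_numpy(dtype=float),
        list(frame.index.astype(str)),
        list(frame.columns.astype(str)),
    )


def write_exposures(exposures: ExposureMatrix, path: str | Path) -> None:
    """Write exposures as TSV with samples as rows (transposed vs. catalogues)."""
    exposures.to_frame().to_csv(path, sep="\t", float_format="%.17g")
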