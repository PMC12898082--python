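"""Spectrum data model, integer-resolution binning, and NIST-style MSP I/O.

Spectra live on a fixed integer m/z grid of length ``D`` (default 500),
where vector index ``k`` corresponds to m/z ``k + 1``.  Training targets are
L1-normalized, i.e. treated as discrete probability distributions over
fragment masses.

The MSP dialect read and written here is the plain-text ``Name:`` /
``MW:`` / ``Num Peaks:`` record format used by NIST-style libraries, with
peak pairs separated by whitespace or semicolons.  A file written by
:func:`write_msp`, read back and written again is byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MAX_MZ = 500


class MspFormatError(ValueError):
    """Malformed MSP record; message carries the offending line number."""


@dataclass
class Spectrum:
    """Nonnegative intensity vector on the integer m/z grid.

    ``intensities[k]`` is the intensity at m/z ``k + 1``.
    """

    intensities: np.ndarray
    normalized: bool = False
    mono_mass: float | None = None
    structure_key: str | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 1:
            raise ValueError("spectrum must be a 1-D vector")
        if np.any(self.intensities < 0):
            raise ValueError("spectrum intensities must be nonnegative")
        if self.normalized and not math.isclose(
            self.intensities.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("normalized spectrum must sum to 1")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def mz_values(self) -> np.ndarray:
        return np.arange(1, len(self) + 1, dtype=np.float64)

    def peaks(self) -> list[tuple[int, float]]:
        """Nonzero (m/z, intensity) pairs in ascending m/z order."""
        idx = np.nonzero(self.intensities)[0]
        return [(int(k) + 1, float(self.intensities[k])) for k in idx]


def bin_peaks(
    peaks, max_mz: int = DEFAULT_MAX_MZ,
    mono_mass: float | None = None, structure_key: str | None = None,
) -> Spectrum:
    """Bin (m/z, intensity) pairs to the integer grid.

    m/z is rounded half away from zero; intensities landing in the same bin
    are summed; peaks rounding below 1 or above ``max_mz`` are dropped (the
    count is logged).  The result is not normalized.
    """
    out = np.zeros(max_mz, dtype=np.float64)
    n_dropped = 0
    for mz, intensity in peaks:
        if intensity < 0:
            raise ValueError(f"negative intensity {intensity} at m/z {mz}")
        nominal = int(math.floor(abs(mz) + 0.5)) * (1 if mz >= 0 else -1)
        if nominal < 1 or nominal > max_mz:
            n_dropped += 1
            continue
        out[nominal - 1] += intensity
    if n_dropped:
        logger.debug("bin_peaks dropped %d out-of-range peaks", n_dropped)
    return Spectrum(out, normalized=False, mono_mass=mono_mass,
                    structure_key=structure_key)


def l1_normalize(s: Spectrum) -> Spectrum:
    """Scale a spectrum so its intensities sum to 1 (idempotent)."""
    total = s.intensities.sum()
    if total <= 0:
        raise ValueError("cannot L1-normalize an all-zero spectrum")
    return replace(s, intensities=s.intensities / total, normalized=True)


# -- MSP reading and writing --------------------------------------------------

_PAIR_SEPARATORS = (";",)


def _parse_peak_line(line: str, lineno: int) -> list[tuple[float, float]]:
    text = line
    for sep in _PAIR_SEPARATORS:
        text = text.replace(sep, " ")
    tokens = text.split()
    if len(tokens) % 2 != 0:
        raise MspFormatError(f"line {lineno}: odd number of peak tokens: {line!r}")
    try:
        values = [float(t) for t in tokens]
    except ValueError as exc:
        raise MspFormatError(f"line {lineno}: non-numeric peak value: {line!r}") from exc
    return list(zip(values[::2], values[1::2]))


def read_msp(path, max_mz: int = DEFAULT_MAX_MZ) -> list[tuple[dict, Spectrum]]:
    """Parse an MSP library file into (metadata, binned Spectrum) records.

    Accepts ``Header: value`` lines (``Name``, ``MW``, ``SMILES``, ...)
    followed by ``Num Peaks: n`` and n whitespace- or semicolon-separated
    peak pairs.  Records whose peak count disagrees with ``Num Peaks`` raise
    :class:`MspFormatError` with the line number; zero-peak records are
    skipped with a warning.
    """
    records: list[tuple[dict, Spectrum]] = []
    metadata: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    expected: int | None = None
    record_line = 0

    def flush(lineno: int):
        nonlocal metadata, peaks, expected
        if expected is None and not metadata:
            return
        if expected is None:
            raise MspFormatError(
                f"line {lineno}: record {metadata.get('Name', '?')!r} "
                "has no 'Num Peaks:' header")
        if len(peaks) != expected:
            raise MspFormatError(
                f"line {lineno}: record {metadata.get('Name', '?')!r} declares "
                f"{expected} peaks but lists {len(peaks)}")
        if expected == 0:
            logger.warning("skipping zero-peak record %r",
                           metadata.get("Name", "?"))
        else:
            mw = metadata.get("MW")
            spectrum = bin_peaks(
                peaks, max_mz=max_mz,
                mono_mass=float(mw) if mw is not None else None,
                structure_key=metadata.get("SMILES"),
            )
            records.append((dict(metadata), spectrum))
        metadata, peaks, expected = {}, [], None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if expected is not None or metadata:
                    flush(lineno)
                continue
            if expected is not None:
                peaks.extend(_parse_peak_line(line, lineno))
                continue
            if ":" not in line:
                raise MspFormatError(f"line {lineno}: expected 'Header: value', "
                                     f"got {line!r}")
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if not metadata:
                record_line = lineno
            if key.lower() == "num peaks":
                try:
                    expected = int(value)
                except ValueError as exc:
                    raise MspFormatError(
                        f"line {lineno}: bad peak count {value!r}") from exc
            else:
                metadata[key] = value
        flush(lineno if "lineno" in locals() else record_line)
    return records


def _format_number(x: float) -> str:
    return format(x, "g")


def write_msp(records, path) -> None:
    """Write (metadata, Spectrum) records as an MSP library file.

    Metadata keys are emitted in insertion order with ``Name`` forced first;
    peaks are the spectrum's nonzero integer bins, one pair per line.
    """
    with open(path, "w") as fh:
        for metadata, spectrum in records:
            keys = list(metadata)
            if "Name" in keys:
                keys.remove("Name")
                keys.insert(0, "Name")
            for key in keys:
                fh.write(f"{key}: {metadata[key]}\n")
            peaks = spectrum.peaks()
            fh.write(f"Num Peaks: {len(peaks)}\n")
            for mz, intensity in peaks:
                fh.write(f"{mz} {_format_number(intensity)}\n")
            fh.write("\n")


def spectra_to_csv(records, path) -> None:
    """Export binned intensity vectors as CSV (one row per record)."""
    import pandas as pd

    rows = {md.get("Name", f"record_{i}"): s.intensities
            for i, (md, s) in enumerate(records)}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [k + 1 for k in range(frame.shape[1])]
    frame.to_csv(path, index_label="Name")
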