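"""Parsing and validation of breath-by-breath VO2 series and baseline settings.

Input conventions follow the metabolic-cart export dialect: the decimal
separator is the point, the comma is reserved as a thousands separator (and is
therefore *not* accepted as a field delimiter), and times are given either as
plain seconds or as ``hh:mm:ss``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Union

import numpy as np

from .exceptions import ConfigError, ParseError, ValidationError

Phase = Literal["exercise", "recovery"]

#: VO2 above this (ml·min⁻¹) is rejected as a probable unit mistake
#: (e.g. L·min⁻¹ data scaled wrong); no human exceeds ~7000 ml·min⁻¹.
VO2_MAX_PLAUSIBLE = 10_000.0

_NUMERAL_RE = re.compile(
    r"""^[+-]?
         (?:
            \d{1,3}(?:,\d{3})+   # grouped integer part, e.g. 1,234 or 12,345,678
          | \d+                  # plain integer part
          | (?=\.\d)             # or empty (allow ".5")
         )
         (?:\.\d*)?              # optional decimal part
       $""",
    re.VERBOSE,
)

_HMS_RE = re.compile(r"^(\d+):([0-5]?\d):([0-5]?\d(?:\.\d*)?)$")


def parse_number(text: str) -> float:
    """Parse a numeral with point decimal separator and optional comma thousands.

    Examples: ``"1,234.5"`` → 1234.5, ``"0"`` → 0.0.

    Raises
    ------
    ParseError
        If the token is empty, contains letters, has more than one decimal
        point, or uses commas anywhere but as well-formed thousands groups.
    """
    token = text.strip()
    if not token:
        raise ParseError("empty numeral")
    if not _NUMERAL_RE.match(token):
        raise ParseError(f"malformed numeral: {token!r}")
    return float(token.replace(",", ""))


def parse_time(text: str) -> float:
    """Parse a duration as plain seconds or ``hh:mm:ss`` into seconds.

    Minutes and seconds fields must lie in [0, 60); the hours field is
    unbounded. Plain numerals pass through as seconds.
    """
    token = text.strip()
    if ":" in token:
        m = _HMS_RE.match(token)
        if not m:
            raise ParseError(f"malformed time (expect h+:mm:ss, mm/ss < 60): {token!r}")
        h, mnt, s = m.groups()
        return 3600.0 * int(h) + 60.0 * int(mnt) + float(s)
    value = parse_number(token)
    if value < 0:
        raise ParseError(f"negative time: {token!r}")
    return value


@dataclass(frozen=True)
class BreathSeries:
    """A time-ordered VO2 record for one phase of a test.

    Parameters
    ----------
    times : array of float
        Seconds since series start; strictly increasing, first element 0 after
        normalization by the reader.
    vo2 : array of float
        Oxygen uptake in ml·min⁻¹; non-negative and finite.
    phase : {"exercise", "recovery"}
    """

    times: np.ndarray
    vo2: np.ndarray
    phase: Phase

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        vo2 = np.asarray(self.vo2, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "vo2", vo2)
        if self.phase not in ("exercise", "recovery"):
            raise ValidationError(f"unknown phase: {self.phase!r}")
        if times.ndim != 1 or vo2.ndim != 1 or times.shape != vo2.shape:
            raise ValidationError("times and vo2 must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValidationError("a breath series needs at least 2 samples")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(vo2))):
            raise ValidationError("non-finite values in series")
        if times[0] < 0:
            raise ValidationError("negative start time")
        dt = np.diff(times)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            if dt[i] == 0:
                raise ValidationError(f"duplicate timestamp at index {i + 1}")
            raise ValidationError(f"non-monotonic time at index {i + 1}")
        if np.any(vo2 < 0):
            raise ValidationError("negative VO2 value")
        if np.any(vo2 > VO2_MAX_PLAUSIBLE):
            raise ValidationError(
                f"VO2 above {VO2_MAX_PLAUSIBLE:g} ml·min⁻¹ — check input units"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Elapsed seconds from first to last sample."""
        return float(self.times[-1] - self.times[0])


BaselineMode = Literal["ignore", "measured", "fixed_per_kg"]


@dataclass(frozen=True)
class BaselineSpec:
    """How the resting-VO2 baseline is obtained.

    ``ignore`` resolves to 0; ``measured`` uses a measured rate in ml·min⁻¹;
    ``fixed_per_kg`` uses a per-kg convention (default 3.5 ml·kg⁻¹·min⁻¹, the
    standard 1-MET resting rate) times body mass.
    """

    mode: BaselineMode
    measured_value: float | None = None
    per_kg_value: float = 3.5
    body_mass: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "ignore":
            pass
        elif self.mode == "measured":
            if self.measured_value is None:
                raise ConfigError("baseline mode 'measured' requires measured_value")
            if self.measured_value < 0:
                raise ConfigError("measured baseline must be >= 0")
        elif self.mode == "fixed_per_kg":
            if self.body_mass is None:
                raise ConfigError("baseline mode 'fixed_per_kg' requires body_mass")
            if self.body_mass <= 0:
                raise ConfigError("body mass must be > 0")
            if self.per_kg_value < 0:
                raise ConfigError("per-kg baseline must be >= 0")
        else:
            raise ConfigError(f"unknown baseline mode: {self.mode!r}")


def resolve_baseline(spec: BaselineSpec) -> float:
    """Resolve a :class:`BaselineSpec` to a rate in ml·min⁻¹."""
    if spec.mode == "ignore":
        return 0.0
    if spec.mode == "measured":
        assert spec.measured_value is not None
        return float(spec.measured_value)
    assert spec.body_mass is not None
    return float(spec.per_kg_value * spec.body_mass)


def _split_fields(line: str) -> list[str]:
    # tab or semicolon first; comma never delimits (it is a thousands
    # separator); otherwise runs of whitespace
    if "\t" in line:
        return [f for f in line.split("\t") if f.strip()]
    if ";" in line:
        return [f for f in line.split(";") if f.strip()]
    return line.split()


def read_breath_series(
    source: Union[str, IO[str], Iterable[str]],
    phase: Phase,
) -> BreathSeries:
    """Read a two-column (time, VO2) delimited text stream into a BreathSeries.

    ``source`` may be a file path, an open text stream, or an iterable of
    lines. Fields are separated by tab, semicolon, or runs of whitespace.
    A single header line is skipped automatically when its fields fail
    numeric parsing. Times are normalized so the series starts at 0 (the time
    column may be a cumulative clock).
    """
    if isinstance(source, str) and "\n" not in source and "\t" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            return read_breath_series(fh, phase)
    if isinstance(source, str):
        source = io.StringIO(source)

    times: list[float] = []
    vo2: list[float] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = _split_fields(line)
        if len(fields) != 2:
            raise ParseError(
                f"line {lineno}: expected 2 columns (time, VO2), got {len(fields)}"
            )
        t_err = v_err = None
        try:
            t = parse_time(fields[0])
        except ParseError as e:
            t_err = e
        try:
            v = parse_number(fields[1])
        except ParseError as e:
            v_err = e
        if t_err or v_err:
            if lineno == 1 and not times and t_err and v_err:
                continue  # header row: both columns non-numeric
            raise t_err or v_err  # type: ignore[misc]
        times.append(t)
        vo2.append(v)

    if len(times) < 2:
        raise ValidationError(f"need at least 2 data rows, got {len(times)}")
    t_arr = np.asarray(times) - times[0]
    return BreathSeries(times=t_arr, vo2=np.asarray(vo2), phase=phase)
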