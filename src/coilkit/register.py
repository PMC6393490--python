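"""Heptad-register assignments and discontinuity classification.

A coiled-coil register maps residue numbers to the seven interface letters
a-g.  Registers are inputs here (no prediction from sequence): they are
written in a small text format of semicolon-separated segments, e.g. ::

    23-78:a..g;79-82:abcd;83-139:a..g

``a..g`` denotes cyclic propagation starting at ``a`` (override the start
with ``a..g,phase=X``); any other pattern is a literal letter string whose
length must equal the segment length.  A literal four-letter ``abcd``
segment is the classic stutter insert: downstream a-positions shift by +4
relative to the regular extrapolation and the supercoil locally underwinds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import RegisterFormatError

log = logging.getLogger(__name__)

LETTERS = "abcdefg"


@dataclass
class HeptadAssignment:
    """Residue-number -> register-letter mapping plus the defining segments."""

    letters: dict[int, str]
    segments: list[tuple[int, int, str]] = field(default_factory=list)

    def letter(self, number: int) -> str | None:
        return self.letters.get(number)

    def positions(self, letter: str) -> list[int]:
        return sorted(n for n, l in self.letters.items() if l == letter)

    def residue_range(self) -> tuple[int, int]:
        nums = sorted(self.letters)
        return nums[0], nums[-1]


@dataclass(frozen=True)
class Heptad:
    """One Table-row heptad addressed by its a-position.

    ``a_prime`` is a+7 in regular repeats (the start of the next heptad on
    the regular extrapolation); ``d`` is the core d position between them.
    ``regular`` is False for a row that spans a register insert — the row's
    arithmetic shape is indistinguishable from a regular one (a stutter row
    still reads (a, a+7, a+3)), so regularity must be recorded explicitly.
    """

    a: int
    a_prime: int
    d: int
    regular: bool = True

    def __post_init__(self) -> None:
        if not self.a < self.d < self.a_prime:
            raise ValueError(f"heptad requires a < d < a' (got {self.a}, {self.d}, {self.a_prime})")


_KINDS = {4: "stutter", 3: "stammer", 1: "skip"}


@dataclass(frozen=True)
class Discontinuity:
    start: int
    end: int
    kind: str
    insert_length: int


def parse_register(spec: str) -> HeptadAssignment:
    """Parse the documented register-spec text into an assignment."""
    letters: dict[int, str] = {}
    segments: list[tuple[int, int, str]] = []
    for raw in spec.replace("\n", ";").split(";"):
        seg = raw.strip()
        if not seg or seg.startswith("#"):
            continue
        try:
            span, pattern = seg.split(":", 1)
            start_s, end_s = span.split("-", 1)
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise RegisterFormatError(f"bad segment {seg!r}: expected START-END:PATTERN") from exc
        if end < start:
            raise RegisterFormatError(f"bad segment {seg!r}: end before start")
        pattern = pattern.strip()
        phase = "a"
        if "," in pattern:
            pattern, modifier = (p.strip() for p in pattern.split(",", 1))
            if not modifier.startswith("phase="):
                raise RegisterFormatError(f"bad modifier in segment {seg!r}")
            phase = modifier[len("phase="):]
            if phase not in LETTERS:
                raise RegisterFormatError(f"phase letter {phase!r} outside a-g in {seg!r}")
        if pattern == "a..g":
            seg_letters = [LETTERS[(LETTERS.index(phase) + i) % 7] for i in range(end - start + 1)]
        else:
            if len(pattern) != end - start + 1:
                raise RegisterFormatError(
                    f"literal pattern length {len(pattern)} != segment length "
                    f"{end - start + 1} in {seg!r}")
            bad = set(pattern) - set(LETTERS)
            if bad:
                raise RegisterFormatError(f"letters outside a-g in {seg!r}: {sorted(bad)}")
            seg_letters = list(pattern)
        for num, letter in zip(range(start, end + 1), seg_letters):
            if num in letters:
                raise RegisterFormatError(f"segment {seg!r} overlaps residue {num}")
            letters[num] = letter
        segments.append((start, end, pattern if pattern != "a..g" else f"a..g,phase={phase}"))
    if not letters:
        raise RegisterFormatError("empty register specification")
    segments.sort()
    return HeptadAssignment(letters=letters, segments=segments)


def serialize_register(assign: HeptadAssignment) -> str:
    """Inverse of :func:`parse_register` (on the segment representation)."""
    parts = []
    for start, end, pattern in assign.segments:
        if pattern.startswith("a..g,phase="):
            phase = pattern[-1]
            pattern = "a..g" if phase == "a" else f"a..g,phase={phase}"
        parts.append(f"{start}-{end}:{pattern}")
    return ";".join(parts)


def read_register(path: str | Path) -> HeptadAssignment:
    return parse_register(Path(path).read_text())


def enumerate_heptads(assign: HeptadAssignment) -> list[Heptad]:
    """One heptad per a-position that has a following a-position.

    For regular repeats the following a-position is a+7 and d is the core
    position between them.  Across an insert (stutter etc.) the row keeps
    a' = a+7 — the start of the next heptad on the regular extrapolation —
    with d the d-lettered residue of the literal insert, so a stutter row
    reads (a, a+7, a+3) even though the next assigned a sits at a+4+7.
    """
    a_positions = assign.positions("a")
    heptads: list[Heptad] = []
    for i, a in enumerate(a_positions[:-1]):
        next_a = a_positions[i + 1]
        d_between = [n for n in range(a + 1, next_a) if assign.letters.get(n) == "d"]
        if not d_between:
            log.debug("a-position %d: no d position before next a, dropped", a)
            continue
        if next_a - a == 7:
            heptads.append(Heptad(a=a, a_prime=next_a, d=d_between[0]))
        else:
            # discontinuity: a' is the regular extrapolation a+7 when assigned
            a_prime = a + 7
            if a_prime not in assign.letters:
                log.debug("a-position %d: a+7 unassigned across insert, dropped", a)
                continue
            heptads.append(Heptad(a=a, a_prime=a_prime, d=d_between[0],
                                  regular=False))
    return heptads


def detect_discontinuities(assign: HeptadAssignment) -> list[Discontinuity]:
    """Classify breaks in cyclic letter propagation by insert length mod 7.

    Walking the assignment in residue order, a point where the letter jumps
    by ``g`` extra steps (mod 7) marks the end of an insert of length
    ``(7 - g) mod 7``; the insert is the run of residues just before the
    break.  Insert lengths 4/3/1 are the canonical stutter/stammer/skip.
    """
    nums = sorted(assign.letters)
    out: list[Discontinuity] = []
    for prev, cur in zip(nums, nums[1:]):
        if cur != prev + 1:
            continue  # gap in coverage, not a register discontinuity
        step = (LETTERS.index(assign.letters[cur])
                - LETTERS.index(assign.letters[prev])) % 7
        skipped = (step - 1) % 7
        if skipped == 0:
            continue
        insert_length = (7 - skipped) % 7
        out.append(Discontinuity(
            start=cur - insert_length,
            end=cur - 1,
            kind=_KINDS.get(insert_length, "irregular"),
            insert_length=insert_length,
        ))
    return out
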