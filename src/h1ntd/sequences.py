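"""Sequence-level analysis of linker-histone N-terminal domains (NTDs).

The H1 NTD is an intrinsically disordered, Lys/Arg-rich tail whose basic
subregion (the stretch between the first and last basic residue, adjoining
the globular domain) mediates DNA binding.  This module provides:

* extraction of the basic subregion under two definitions,
* composition statistics (length, Arg/Lys content, Pro/Gly "breaker" count),
* ideal-helix helical-wheel projection (3.6 residues/turn, 100 deg/residue)
  with detection of the basic "face" -- the angular arc concentrating the
  most Arg/Lys sidechains,
* a tabular per-subtype report.

His is treated as neutral throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import pandas as pd

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
BASIC_AA = set("KR")
BREAKER_AA = set("PG")
ACIDIC_AA = set("DE")

SubregionVariant = Literal["span-first-to-last-basic", "three-before-first-lys"]


class NoBasicResiduesError(ValueError):
    """Raised when a sequence contains no Lys/Arg residue."""


@dataclass(frozen=True)
class NTDSequence:
    """An NTD peptide sequence with 1-based residue numbering.

    Parameters
    ----------
    subtype_id : short label such as ``"H1.0"``.
    residues : one-letter amino-acid string (standard 20 codes only).
    first_index : residue number of the first residue (default 1).
    """

    subtype_id: str
    residues: str
    first_index: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_index(self) -> int:
        return self.first_index + len(self.residues) - 1

    def residue(self, index: int) -> str:
        """One-letter code of the residue with the given (1-based) number."""
        if not self.first_index <= index <= self.last_index:
            raise IndexError(f"residue {index} outside {self.first_index}..{self.last_index}")
        return self.residues[index - self.first_index]

    def numbered(self) -> list[tuple[int, str]]:
        return [(self.first_index + i, aa) for i, aa in enumerate(self.residues)]


@dataclass(frozen=True)
class BasicSubregion:
    """An inclusive residue span of an NTD, holding its basic segment."""

    parent: NTDSequence
    start_index: int
    end_index: int
    definition_variant: SubregionVariant = "span-first-to-last-basic"

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")
        if not (
            self.parent.first_index <= self.start_index
            and self.end_index <= self.parent.last_index
        ):
            raise ValueError("subregion outside parent sequence")
        if self.definition_variant == "span-first-to-last-basic":
            if (
                self.parent.residue(self.start_index) not in BASIC_AA
                or self.parent.residue(self.end_index) not in BASIC_AA
            ):
                raise ValueError("span-first-to-last-basic must start and end on K/R")

    @property
    def residues(self) -> str:
        p = self.parent
        return p.residues[self.start_index - p.first_index : self.end_index - p.first_index + 1]

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    def numbered(self) -> list[tuple[int, str]]:
        return [(self.start_index + i, aa) for i, aa in enumerate(self.residues)]


@dataclass(frozen=True)
class CompositionStats:
    """Length / basic / breaker composition of a residue span.

    ``pct_basic`` is 100*n_basic/length truncated (not rounded) to one
    decimal, the convention of the reference subtype table.
    """

    length: int
    n_basic: int
    pct_basic: float
    n_breaker: int


@dataclass(frozen=True)
class WheelProjection:
    """Helical-wheel projection with the detected basic face.

    Angles are ``((i - start) * 100) mod 360`` degrees for residue number
    ``i`` -- an ideal alpha helix seen down its axis (3.6 residues/turn).
    The face is the arc of configurable width whose half-open angular
    interval ``[a, a + width)`` contains the largest number of K/R residues;
    ties are broken by the smallest start angle (scanned in 1-degree steps).
    """

    residue_numbers: tuple[int, ...]
    residue_codes: tuple[str, ...]
    angles_deg: tuple[float, ...]
    face_width_deg: float
    face_start_deg: float
    basic_face_members: tuple[int, ...]

    def in_face(self, index: int) -> bool:
        i = self.residue_numbers.index(index)
        return _in_arc(self.angles_deg[i], self.face_start_deg, self.face_width_deg)

    def to_frame(self) -> pd.DataFrame:
        """Per-residue table: number, code, angle, charge class, in_face."""
        rows = []
        for num, aa, ang in zip(self.residue_numbers, self.residue_codes, self.angles_deg):
            rows.append(
                {
                    "residue": num,
                    "code": aa,
                    "angle_deg": ang,
                    "charge_class": _charge_class(aa),
                    "in_face": _in_arc(ang, self.face_start_deg, self.face_width_deg),
                }
            )
        return pd.DataFrame(rows)


def _charge_class(aa: str) -> str:
    if aa in BASIC_AA:
        return "basic"
    if aa in ACIDIC_AA:
        return "acidic"
    return "neutral"  # His deliberately neutral


def _in_arc(angle: float, start: float, width: float) -> bool:
    return ((angle - start) % 360.0) < width


def truncate_percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator truncated to one decimal place."""
    return math.floor(1000.0 * numerator / denominator) / 10.0


def round_percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded (half away from zero) to one decimal."""
    return math.floor(1000.0 * numerator / denominator + 0.5) / 10.0


def extract_basic_subregion(
    seq: NTDSequence, variant: SubregionVariant = "span-first-to-last-basic"
) -> BasicSubregion:
    """Extract the basic subregion of an NTD.

    ``span-first-to-last-basic``: the inclusive segment between the first and
    last Arg/Lys residue (the convention of the subtype composition table).

    ``three-before-first-lys``: starts one helical turn (three residues)
    before the first Lys/Arg -- clamped to the first residue -- and runs to
    the NTD's last residue (the convention used to carve out simulation
    constructs).
    """
    basic_positions = [num for num, aa in seq.numbered() if aa in BASIC_AA]
    if not basic_positions:
        raise NoBasicResiduesError(f"{seq.subtype_id}: no basic residues (K/R) present")
    if variant == "span-first-to-last-basic":
        return BasicSubregion(seq, basic_positions[0], basic_positions[-1], variant)
    if variant == "three-before-first-lys":
        start = max(seq.first_index, basic_positions[0] - 3)
        return BasicSubregion(seq, start, seq.last_index, variant)
    raise ValueError(f"unknown subregion variant: {variant!r}")


def composition_stats(sub: BasicSubregion | NTDSequence) -> CompositionStats:
    """Length, Arg/Lys and Pro/Gly counts of a span, with truncated percent."""
    residues = sub.residues
    n_basic = sum(aa in BASIC_AA for aa in residues)
    n_breaker = sum(aa in BREAKER_AA for aa in residues)
    return CompositionStats(
        length=len(residues),
        n_basic=n_basic,
        pct_basic=truncate_percent(n_basic, len(residues)),
        n_breaker=n_breaker,
    )


def helical_wheel(
    sub: BasicSubregion | NTDSequence, face_width_deg: float = 180.0
) -> WheelProjection:
    """Project a span onto an ideal helical wheel and find the basic face."""
    numbered = sub.numbered()
    if len(numbered) < 2:
        raise ValueError("helical wheel needs at least 2 residues")
    start_num = numbered[0][0]
    numbers = tuple(num for num, _ in numbered)
    codes = tuple(aa for _, aa in numbered)
    angles = tuple(float(((num - start_num) * 100) % 360) for num in numbers)

    basic_angles = [ang for ang, aa in zip(angles, codes) if aa in BASIC_AA]
    best_start, best_count = 0.0, -1
    for a in range(360):
        count = sum(_in_arc(ang, float(a), face_width_deg) for ang in basic_angles)
        if count > best_count:
            best_start, best_count = float(a), count
    members = tuple(
        num
        for num, aa, ang in zip(numbers, codes, angles)
        if aa in BASIC_AA and _in_arc(ang, best_start, face_width_deg)
    )
    return WheelProjection(numbers, codes, angles, face_width_deg, best_start, members)


def subtype_report(
    seqs: Iterable[NTDSequence],
    variant: SubregionVariant = "span-first-to-last-basic",
    face_width_deg: float = 180.0,
) -> pd.DataFrame:
    """One row per subtype: subregion composition plus wheel-face summary.

    Columns mirror the subtype composition table (length, Arg/Lys count and
    truncated percentage, Pro/Gly count) and add the full-NTD composition
    (rounded percentage, the body-text convention) and the basic-face
    members.  Rows are sorted by subtype id; duplicate ids are an error.
    """
    seqs = list(seqs)
    ids = [s.subtype_id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subtype ids: {dupes}")
    rows = []
    for seq in sorted(seqs, key=lambda s: s.subtype_id):
        sub = extract_basic_subregion(seq, variant)
        stats = composition_stats(sub)
        wheel = helical_wheel(sub, face_width_deg)
        ntd_basic = sum(aa in BASIC_AA for aa in seq.residues)
        rows.append(
            {
                "subtype": seq.subtype_id,
                "subregion_start": sub.start_index,
                "subregion_end": sub.end_index,
                "length": stats.length,
                "n_basic": stats.n_basic,
                "pct_basic": stats.pct_basic,
                "n_breaker": stats.n_breaker,
                "ntd_length": len(seq),
                "ntd_n_basic": ntd_basic,
                "ntd_pct_basic": round_percent(ntd_basic, len(seq)),
                "face_members": ",".join(f"{seq.residue(n)}{n}" for n in wheel.basic_face_members),
            }
        )
    columns = [
        "subtype", "subregion_start", "subregion_end", "length", "n_basic",
        "pct_basic", "n_breaker", "ntd_length", "ntd_n_basic", "ntd_pct_basic",
        "face_members",
    ]
    return pd.DataFrame(rows, columns=columns)


def load_bundled_ntds() -> list[NTDSequence]:
    """The three bundled human H1 NTD subtype sequences (H1.0, H1.1, H1.2)."""
    from .io import read_fasta

    ref = resources.files("h1ntd.data").joinpath("ntd_sequences.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)
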