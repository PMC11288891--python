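"""Burial-pattern scanning of amyloidogenic sequences against β-strand slots.

A designed peptide-binding cleft buries every other side chain of the bound
β-strand in the scaffold core.  A natural amyloidogenic segment is therefore
compatible with a given design when the residues at the buried (core-facing)
window positions are small or hydrophobic, and no internal position is a
proline (which would break the strand).  This module scans target protein
sequences with such burial-pattern templates, reports every matching window,
and threads matched windows onto template peptides for downstream redesign.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive for biologist-facing output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "BURIED_ALLOWED",
    "CANONICAL_AA",
    "Template",
    "TargetProtein",
    "Match",
    "ThreadedPeptide",
    "scan_sequence",
    "scan_hairpin",
    "thread_match",
    "load_targets",
    "default_templates",
]

#: Residues permitted at solvent-inaccessible (core-facing) window positions.
BURIED_ALLOWED = frozenset("FAMILVSTYG")

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Proline is disallowed at solvent-exposed positions except the window termini.
EXPOSED_DISALLOWED_INTERNAL = frozenset("P")


class SequenceValidationError(ValueError):
    """A sequence or template failed validation; the message names the cause."""


@dataclass(frozen=True)
class Template:
    """A binding-slot description: window length and buried-position mask.

    Parameters
    ----------
    name:
        Label of the design the slot belongs to.
    length:
        Number of residues in the designed peptide (the window size ``n``).
    buried_idx:
        0-based window positions facing the scaffold core.  Must be a
        non-empty subset of ``range(length)``.
    kind:
        ``"single-strand"`` or ``"hairpin"`` (hairpins are scanned as two
        coupled single-strand windows; see :func:`scan_hairpin`).
    """

    name: str
    length: int
    buried_idx: frozenset[int]
    kind: str = "single-strand"

    def __post_init__(self) -> None:
        if not (1 <= self.length <= 30):
            raise SequenceValidationError(
                f"template {self.name!r}: length must be in [1, 30], got {self.length}"
            )
        object.__setattr__(self, "buried_idx", frozenset(self.buried_idx))
        if not self.buried_idx:
            raise SequenceValidationError(
                f"template {self.name!r}: buried_idx must be non-empty"
            )
        bad = sorted(i for i in self.buried_idx if not (0 <= i < self.length))
        if bad:
            raise SequenceValidationError(
                f"template {self.name!r}: buried_idx {bad} outside [0, {self.length})"
            )
        if self.kind not in ("single-strand", "hairpin"):
            raise SequenceValidationError(
                f"template {self.name!r}: kind must be 'single-strand' or 'hairpin'"
            )


@dataclass(frozen=True)
class TargetProtein:
    """An amyloidogenic target sequence (uppercase one-letter codes)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise SequenceValidationError(f"protein {self.name!r}: empty sequence")
        for pos, aa in enumerate(seq):
            if aa not in CANONICAL_AA:
                raise SequenceValidationError(
                    f"protein {self.name!r}: non-canonical residue {aa!r} "
                    f"at position {pos + 1} (1-based)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Match:
    """A window of a target protein compatible with a template's burial pattern."""

    protein: str
    start: int
    end: int
    window_seq: str
    template: str
    buried_residues: str
    orientation: str = "forward"

    @property
    def length(self) -> int:
        return self.end - self.start


class ThreadedPeptide(str):
    """A threaded peptide sequence annotated with its source coordinates."""

    protein: str
    start: int
    end: int

    def __new__(cls, seq: str, *, protein: str, start: int, end: int):
        obj = super().__new__(cls, seq)
        obj.protein = protein
        obj.start = start
        obj.end = end
        return obj


def _window_ok(window: str, template: Template) -> bool:
    n = template.length
    for i, aa in enumerate(window):
        if i in template.buried_idx:
            if aa not in BURIED_ALLOWED:
                return False
        elif aa in EXPOSED_DISALLOWED_INTERNAL and 0 < i < n - 1:
            return False
    return True


def scan_sequence(
    template: Template, protein: TargetProtein, reverse: bool = False
) -> list[Match]:
    """Scan every length-``n`` frame of ``protein`` against ``template``.

    All ``L - n + 1`` frames (stride 1) are evaluated; a frame matches when
    every buried position holds a residue from :data:`BURIED_ALLOWED` and no
    internal exposed position is proline.  Overlapping matches are all
    reported, sorted by start coordinate.

    With ``reverse=True`` the sequence is additionally scanned in reverse
    orientation (N→C of the window paired C→N on the protein); reverse
    matches carry ``orientation="reverse"`` and coordinates on the forward
    strand of the protein.  Off by default: the scan is defined on forward
    frames only.
    """
    seq = protein.sequence
    n = template.length
    matches: list[Match] = []
    for start in range(len(seq) - n + 1):
        window = seq[start : start + n]
        if _window_ok(window, template):
            matches.append(
                Match(
                    protein=protein.name,
                    start=start,
                    end=start + n,
                    window_seq=window,
                    template=template.name,
                    buried_residues="".join(
                        window[i] for i in sorted(template.buried_idx)
                    ),
                )
            )
    if reverse:
        rev = seq[::-1]
        for rstart in range(len(rev) - n + 1):
            window = rev[rstart : rstart + n]
            if _window_ok(window, template):
                start = len(seq) - (rstart + n)
                matches.append(
                    Match(
                        protein=protein.name,
                        start=start,
                        end=start + n,
                        window_seq=window,
                        template=template.name,
                        buried_residues="".join(
                            window[i] for i in sorted(template.buried_idx)
                        ),
                        orientation="reverse",
                    )
                )
    matches.sort(key=lambda m: (m.start, m.orientation))
    return matches


def scan_hairpin(
    strand1: Template,
    strand2: Template,
    protein: TargetProtein,
    loop_lengths: range = range(2, 7),
) -> list[tuple[Match, Match]]:
    """Scan for β-hairpin-compatible pairs of windows.

    A hairpin slot is treated as two independent single-strand windows
    separated by a turn of ``loop_lengths`` residues (an interpretation:
    the two strands must both satisfy their burial patterns and be joined
    by a short loop).  Returns pairs ``(match1, match2)`` with
    ``match2.start - match1.end`` in ``loop_lengths``.
    """
    first = scan_sequence(strand1, protein)
    second = scan_sequence(strand2, protein)
    pairs = [
        (m1, m2)
        for m1, m2 in itertools.product(first, second)
        if (m2.start - m1.end) in loop_lengths
    ]
    return pairs


def thread_match(template_peptide: str, match: Match) -> ThreadedPeptide:
    """Mutate a template designed peptide to the matched natural sequence.

    The substitution is complete — the result is the matched window sequence
    itself, preserving length — and the source protein coordinates travel
    with the result as metadata.
    """
    if len(template_peptide) != match.length:
        raise SequenceValidationError(
            f"template peptide length {len(template_peptide)} != "
            f"match window length {match.length}"
        )
    return ThreadedPeptide(
        match.window_seq, protein=match.protein, start=match.start, end=match.end
    )


# The four amyloidogenic target sequences scanned for binder design:
# amyloid-β 1-42, serum amyloid A1, a tau fragment spanning the repeat
# region, and transthyretin.
_TARGET_SEQUENCES: dict[str, str] = {
    "Abeta42": "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA",
    "SAA1": (
        "RSFFSFLGEAFDGARDMWRAYSDMREANYIGSDKYFHARGNYDAAKRGPGGVWAAEAISDAREN"
        "IQRFFGHGAEDSLADQAANEWGRSGKDPNHFRPAGLPEKY"
    ),
    "tau": (
        "PGGGKVQIINKKLDLSNVQSKCGSKDNIKHVPGGGSVQIVYKPVDLSKVTSKCGSLGNIHHK"
        "PGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGGNKKIETHKLTFRENAKAKTDHGAEIVYK"
    ),
    "TTR": (
        "GPTGTGESKCPLMVKVLDAVRGSPAINVAVHVFRKAADDTWEPFASGKTSESGELHGLTTEEEF"
        "VEGIYKVEIDTKSYWKALGISPFHEHAEVVFTANDSGPRRYTIAALLSPYSYSTTAVVTNPKE"
    ),
}


def load_targets() -> list[TargetProtein]:
    """Return the four bundled amyloidogenic target sequences.

    Aβ42 (42 residues), serum amyloid A1, the tau repeat-region fragment and
    transthyretin, exactly as targeted in the binder-design campaign.
    """
    return [TargetProtein(name, seq) for name, seq in _TARGET_SEQUENCES.items()]


def default_templates() -> list[Template]:
    """Default single-strand slot templates with alternating buried masks.

    A β-strand bound in a deep cleft buries every other side chain, so the
    defaults alternate buried/exposed positions: length 8 with buried mask
    {0,2,4,6}, and length 9 with masks {0,2,4,6,8} and {1,3,5,7} (both
    registers).  Per-design masks, read off each design's structure, can be
    supplied as user :class:`Template` objects instead.
    """
    return [
        Template("slot8_even", 8, frozenset({0, 2, 4, 6})),
        Template("slot9_even", 9, frozenset({0, 2, 4, 6, 8})),
        Template("slot9_odd", 9, frozenset({1, 3, 5, 7})),
    ]
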