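"""Canonical k-mer classes and duplicated-occurrence detection in CNEs.

A motif class is the pair {word, reverse complement} collapsed onto its
lexicographically smaller member ("canonical" word).  For odd k no word is
its own reverse complement, so there are exactly 4**k / 2 classes (512
pentamer classes).  A CNE carries the signature ``c x MOTIF / W bp`` when at
least ``c`` (conserved) occurrences of either class member lie with start
positions at most ``W`` bp apart, all within one element.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cne_builder import ConservedElement

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(word: str) -> str:
    """Lexicographic minimum of {word, revcomp(word)}."""
    rc = revcomp(word)
    return word if word <= rc else rc


@dataclass(frozen=True, order=True)
class MotifClass:
    """A strand-collapsed k-mer: the canonical member of {word, revcomp}."""

    canonical: str

    def __post_init__(self) -> None:
        word = self.canonical
        if not word or any(b not in "ACGT" for b in word):
            raise ValueError(f"motif must be non-empty over ACGT, got {word!r}")
        if word != canonical(word):
            raise ValueError(
                f"{word!r} is not canonical (use MotifClass.from_word)"
            )

    @classmethod
    def from_word(cls, word: str) -> "MotifClass":
        return cls(canonical(word.upper()))

    @property
    def k(self) -> int:
        return len(self.canonical)

    @property
    def members(self) -> tuple[str, str]:
        return (self.canonical, revcomp(self.canonical))


@dataclass(frozen=True)
class MotifOccurrence:
    """One match of a motif class at a fixed offset within a CNE."""

    cne_id: str
    offset: int
    strandword: str   # which class member matched on the forward strand
    conserved: bool   # all k mask bases true


@dataclass(frozen=True)
class SignatureSpec:
    """(motif class, copy count, window) — e.g. the 2xGATTA/125bp tag."""

    motif: MotifClass
    copies: int = 2
    window: int = 125

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")

    @property
    def tag(self) -> str:
        return f"{self.copies}x{self.motif.canonical}/{self.window}bp"


def enumerate_classes(k: int) -> list[MotifClass]:
    """All strand-collapsed k-mer classes, sorted by canonical word.

    Every k-mer over ACGT belongs to exactly one returned class.  For odd k
    the count is 4**k / 2; even k adds one class per palindrome.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for tup in product("ACGT", repeat=k):
        word = "".join(tup)
        if word <= revcomp(word):
            out.append(MotifClass(word))
    return out


def find_occurrences(
    cne: ConservedElement,
    motif: MotifClass,
    require_conserved: bool = True,
) -> list[MotifOccurrence]:
    """All offsets in ``cne`` where either class member matches forward.

    With ``require_conserved`` (the default) an offset only counts when all k
    mask bases under the word are conserved.  Offsets ascend.
    """
    k = motif.k
    fwd, rev = motif.members
    seq = cne.sequence.upper()
    mask = cne.conservation_mask
    out: list[MotifOccurrence] = []
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if word != fwd and word != rev:
            continue
        conserved = bool(mask[i : i + k].all())
        if require_conserved and not conserved:
            continue
        out.append(MotifOccurrence(cne.cne_id, i, word, conserved))
    return out


def has_duplicate(
    occurrences: Sequence[MotifOccurrence] | Sequence[int],
    spec: SignatureSpec,
    window_mode: str = "start",
) -> bool:
    """True iff some c occurrences fit in the window.

    ``window_mode="start"`` (default) uses start-to-start distance: sorted
    offsets satisfy offset[i+c-1] - offset[i] <= W for some i.
    ``window_mode="span"`` requires the whole span, end of last word minus
    start of first, to fit: offset[i+c-1] + k - offset[i] <= W.
    """
    offsets = sorted(
        {
            o.offset if isinstance(o, MotifOccurrence) else int(o)
            for o in occurrences
        }
    )  # c distinct offsets are required
    c, W = spec.copies, spec.window
    if len(offsets) < c:
        return False
    extra = spec.motif.k if window_mode == "span" else 0
    if window_mode not in ("start", "span"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    for i in range(len(offsets) - c + 1):
        if offsets[i + c - 1] - offsets[i] + extra <= W:
            return True
    return False


def _class_offsets(
    cne: ConservedElement, k: int, require_conserved: bool
) -> dict[str, list[int]]:
    """Offsets of every canonical class present in one CNE (single pass)."""
    seq = cne.sequence.upper()
    mask = cne.conservation_mask
    by_class: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if any(b not in "ACGT" for b in word):
            continue
        if require_conserved and not mask[i : i + k].all():
            continue
        by_class.setdefault(canonical(word), []).append(i)
    return by_class


def scan_all(
    elements: Iterable[ConservedElement],
    k: int = 5,
    copies: int = 2,
    window: int = 125,
    require_conserved: bool = True,
    window_mode: str = "start",
) -> dict[str, set[str]]:
    """Incidence of every k-mer class signature across CNEs.

    Returns ``{cne_id: {canonical motifs whose cxW signature the CNE
    carries}}``.  Windows never span two CNEs.  CNEs carrying no signature
    map to the empty set.
    """
    incidence: dict[str, set[str]] = {}
    for cne in elements:
        present: set[str] = set()
        for canon, offs in _class_offsets(cne, k, require_conserved).items():
            spec = SignatureSpec(MotifClass(canon), copies, window)
            if has_duplicate(offs, spec, window_mode=window_mode):
                present.add(canon)
        incidence[cne.cne_id] = present
    return incidence


def write_incidence_tsv(incidence: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("cne_id\tcanonical_motif\n")
        for cne_id in sorted(incidence):
            for canon in sorted(incidence[cne_id]):
                fh.write(f"{cne_id}\t{canon}\n")


def read_incidence_tsv(path) -> dict[str, set[str]]:
    incidence: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cne_id"):
            raise ValueError(f"{path}: missing incidence header")
        for line in fh:
            cne_id, canon = line.rstrip("\n").split("\t")
            incidence.setdefault(cne_id, set()).add(canon)
    return incidence
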