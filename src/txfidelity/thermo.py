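"""Nearest-neighbor free-energy engine for the transcription bubble.

The transcription bubble of an elongation complex consists of a melted
double-stranded DNA window and an RNA/DNA hybrid. The free energy of each
sub-state (PRE, POST, POST.NTP, BACK) is the sum of the DNA/DNA opening
cost, the hybrid formation energy and a constant polymerase term:

    dG_state = dG_DNA/DNA + dG_RNA/DNA + dG_pol

Duplex energies follow the nearest-neighbor model: the energy of a duplex is
the sum of the tabulated dG37 values of its overlapping dinucleotide steps
(pairs of base pairs), so an interior base pair contributes to two steps.
Three duplex classes are distinguished: DNA/DNA, Watson-Crick RNA/DNA, and
RNA/DNA steps containing a single mismatched pair.

Strand conventions: the input sequence is the coding (sense) DNA strand,
5'->3'; the transcript is the coding strand with T->U; the template is its
reverse complement. Positions are 1-based transcript coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"
_DNA_INDEX = {b: i for i, b in enumerate(DNA_BASES)}
_RNA_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

# With A,C,G,T(.U) coded 0..3 the Watson-Crick complement is 3 - code.
def complement_code(code: int) -> int:
    return 3 - code


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, b in enumerate(seq):
        try:
            out[i] = _DNA_INDEX[b]
        except KeyError:
            raise ValueError(f"non-DNA character {b!r} at position {i + 1}") from None
    return out


def transcribe(coding: str) -> str:
    """RNA transcript of a coding-strand DNA sequence (T -> U)."""
    return coding.upper().replace("T", "U")


def rna_complement(rna_base: str) -> str:
    """Template DNA base paired with an RNA base."""
    return {"A": "T", "C": "G", "G": "C", "U": "A"}[rna_base]


def template_mismatch_partner(template_base: str) -> str:
    """Published mismatch identity for a template base (rA.dA, rC.dC, rG.dG, rU.dT)."""
    return {"A": "A", "C": "C", "G": "G", "T": "U"}[template_base]


class DuplexClass(str, Enum):
    DNA_DNA = "DNA_DNA"
    RNA_DNA_WC = "RNA_DNA_WC"
    RNA_DNA_MISMATCH = "RNA_DNA_MISMATCH"


class Substate(str, Enum):
    PRE = "PRE"
    POST = "POST"
    POST_NTP = "POST_NTP"
    BACK = "BACK"


@dataclass(frozen=True)
class DinucStep:
    """One dinucleotide step: two adjacent base pairs of a duplex.

    ``top_5to3`` reads the top strand 5'->3'; ``bottom_3to5`` reads the bottom
    strand 3'->5' so that position k of both strings forms base pair k.
    """

    duplex_class: DuplexClass
    top_5to3: str
    bottom_3to5: str
    mismatch_slot: str = "none"  # none | first | second


class NNTable:
    """Dinucleotide-step dG37 lookup for one duplex class."""

    def __init__(self, duplex_class: DuplexClass, entries: dict[tuple[str, str], float],
                 source_label: str = ""):
        self.duplex_class = duplex_class
        self.entries = dict(entries)
        self.source_label = source_label

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.entries[key]

    @classmethod
    def from_tsv(cls, path_or_buf, duplex_class: DuplexClass, source_label: str = "") -> "NNTable":
        entries = {}
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cls_name, top, bottom, val = line.split("\t")
            if cls_name != duplex_class.value:
                raise ValueError(f"table row class {cls_name} != expected {duplex_class.value}")
            entries[(top, bottom)] = float(val)
        table = cls(duplex_class, entries, source_label)
        table.validate()
        return table

    def validate(self) -> None:
        if self.duplex_class in (DuplexClass.DNA_DNA, DuplexClass.RNA_DNA_WC):
            alphabet = DNA_BASES if self.duplex_class == DuplexClass.DNA_DNA else RNA_BASES
            comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
            for b1 in alphabet:
                for b2 in alphabet:
                    key = (b1 + b2, comp[b1] + comp[b2])
                    if key not in self.entries:
                        raise ValueError(
                            f"corrupt {self.duplex_class.value} table: missing WC step {key}")


@dataclass
class NNTableSet:
    """The three duplex-class tables plus bookkeeping of fallback substitutions."""

    dna_dna: NNTable
    rna_dna_wc: NNTable
    rna_dna_mismatch: NNTable
    fallback_log: dict = field(default_factory=dict)

    def record_fallback(self, requested: tuple[str, str], used: tuple[str, str]) -> None:
        n = self.fallback_log.get((requested, used), 0)
        if n == 0:
            logger.info("mismatch NN fallback: %s -> grouped entry %s", requested, used)
        self.fallback_log[(requested, used)] = n + 1


def load_default_tables() -> NNTableSet:
    """Load the tables shipped with the package.

    The mismatch table is a synthetic stand-in (see its file header): the
    published mismatch set is approximated by Watson-Crick values plus a
    context-varying penalty whose single-step mean is +0.9 kcal/mol.
    """
    data = resources.files("txfidelity.data")
    with (data / "dna_dna.tsv").open() as fh:
        dna = NNTable.from_tsv(fh, DuplexClass.DNA_DNA, "SantaLucia 1998 unified")
    with (data / "rna_dna_wc.tsv").open() as fh:
        wc = NNTable.from_tsv(fh, DuplexClass.RNA_DNA_WC, "Sugimoto 1995")
    with (data / "rna_dna_mismatch_synthetic.tsv").open() as fh:
        mm = NNTable.from_tsv(fh, DuplexClass.RNA_DNA_MISMATCH, "synthetic stand-in")
    return NNTableSet(dna, wc, mm)


def lookup_step_dG(tables: NNTableSet, step: DinucStep) -> float:
    """dG37 of one dinucleotide step.

    Watson-Crick steps must be present (a missing one means the table is
    corrupt). An uncatalogued mismatch resolves through the fallback rule:
    the mismatched RNA base is replaced by the published mismatch identity
    for the same template base, and the substitution is recorded.
    """
    if step.duplex_class == DuplexClass.DNA_DNA:
        return tables.dna_dna[(step.top_5to3, step.bottom_3to5)]
    if step.duplex_class == DuplexClass.RNA_DNA_WC:
        return tables.rna_dna_wc[(step.top_5to3, step.bottom_3to5)]

    key = (step.top_5to3, step.bottom_3to5)
    if key in tables.rna_dna_mismatch:
        return tables.rna_dna_mismatch[key]
    if step.mismatch_slot not in ("first", "second"):
        raise ValueError("mismatch step must declare its mismatched slot")
    slot = 0 if step.mismatch_slot == "first" else 1
    top = list(step.top_5to3)
    top[slot] = template_mismatch_partner(step.bottom_3to5[slot])
    fb_key = ("".join(top), step.bottom_3to5)
    if fb_key not in tables.rna_dna_mismatch:
        raise KeyError(f"no mismatch entry for {key} nor fallback {fb_key}")
    tables.record_fallback(key, fb_key)
    return tables.rna_dna_mismatch[fb_key]


def duplex_dG(tables: NNTableSet, top: str, bottom: str,
              mismatch_offsets: frozenset[int] | set[int] = frozenset(),
              duplex_class: DuplexClass = DuplexClass.RNA_DNA_WC) -> float:
    """Total dG37 of a duplex as the sum over its L-1 overlapping steps.

    ``mismatch_offsets`` are offsets from the 3' end of the top strand
    (0 = last base). A mismatched pair contributes mismatch parameters to
    both steps that contain it; two consecutive mismatches are rejected
    (the model forbids them).
    """
    L = len(top)
    if L < 2:
        raise ValueError("duplex shorter than 2 bp has no nearest-neighbor step")
    if len(bottom) != L:
        raise ValueError("strand lengths differ")
    mm_idx = {L - 1 - off for off in mismatch_offsets}
    for i in mm_idx:
        if i + 1 in mm_idx:
            raise ValueError("two consecutive mismatches are not modeled")
    total = 0.0
    for i in range(L - 1):
        first_mm = i in mm_idx
        second_mm = (i + 1) in mm_idx
        if duplex_class == DuplexClass.DNA_DNA or not (first_mm or second_mm):
            cls = duplex_class
            slot = "none"
        else:
            cls = DuplexClass.RNA_DNA_MISMATCH
            slot = "first" if first_mm else "second"
        total += lookup_step_dG(
            tables, DinucStep(cls, top[i:i + 2], bottom[i:i + 2], slot))
    return total


@dataclass(frozen=True)
class BubbleGeometry:
    melted_dna_bp: int = 12
    hybrid_bp: int = 9

    def __post_init__(self):
        if not (2 <= self.hybrid_bp <= self.melted_dna_bp):
            raise ValueError("require 2 <= hybrid_bp <= melted_dna_bp")
        if self.hybrid_bp not in (8, 9):
            raise ValueError("hybrid length must be 8 or 9 bp")


@dataclass(frozen=True)
class BubbleState:
    """The transcription-bubble configuration of one sub-state."""

    template_pos: int                 # i, last incorporated transcript nucleotide
    substate: Substate
    transcript_3prime: str            # RNA covering the hybrid window, 5'->3'
    mismatch_offsets: frozenset[int]  # offsets from the transcript 3' end
    dG_dna_dna: float
    dG_rna_dna: float
    dG_pol: float

    @property
    def dG_state(self) -> float:
        return self.dG_dna_dna + self.dG_rna_dna + self.dG_pol


class PositionOutOfRange(ValueError):
    """The full bubble window does not fit inside the template."""


def bubble_windows(i: int, substate: Substate, geom: BubbleGeometry
                   ) -> tuple[tuple[int, int], tuple[int, int]]:
    """1-based inclusive (hybrid, melted-DNA) windows of sub-state ``substate``
    of elongation state E_i.

    POST keeps the active site at i+1 free, so its hybrid is one bp shorter
    than PRE's; BACK shifts the register back by one with the 3' nucleotide
    extruded into the backtrack pocket (unpaired).
    """
    h, m = geom.hybrid_bp, geom.melted_dna_bp
    if substate == Substate.PRE:
        return (i - h + 1, i), (i - h + 1, i - h + m)
    if substate == Substate.POST:
        return (i - h + 2, i), (i - h + 2, i - h + m + 1)
    if substate == Substate.POST_NTP:
        return (i - h + 2, i + 1), (i - h + 2, i - h + m + 1)
    if substate == Substate.BACK:
        return (i - h, i - 1), (i - h, i - h + m - 1)
    raise ValueError(substate)


def build_bubble_state(coding_seq: str, i: int, substate: Substate,
                       tables: NNTableSet, geom: BubbleGeometry,
                       candidate: str | None = None,
                       mismatch_offsets: frozenset[int] | set[int] = frozenset(),
                       dG_pol: float = 0.0) -> BubbleState:
    """Bubble free energies of sub-state ``substate`` of elongation state E_i.

    ``mismatch_offsets`` count from the 3' end of the *transcript* (0 = the
    last incorporated nucleotide i, 1 = i-1). For POST_NTP, ``candidate`` is
    the RNA base held in the active site opposite template position i+1; a
    non-cognate candidate adds a mismatched newest pair.
    """
    coding_seq = coding_seq.upper()
    L = len(coding_seq)
    (ha, hb), (ma, mb) = bubble_windows(i, substate, geom)
    if ma < 1 or mb > L or ha < 1 or hb > L:
        raise PositionOutOfRange(
            f"bubble of E_{i} ({substate.value}) spans {ma}..{mb}, template has 1..{L}")

    rna_full = transcribe(coding_seq)
    mm_abs = set()
    for off in mismatch_offsets:
        p = i - off
        if not (1 <= p <= i):
            raise ValueError(f"mismatch offset {off} outside transcript")
        mm_abs.add(p)

    top = list(rna_full[ha - 1:hb])
    if substate == Substate.POST_NTP:
        if candidate is None:
            raise ValueError("POST_NTP requires a candidate base")
        if candidate not in RNA_BASES:
            raise ValueError(f"invalid RNA base {candidate!r}")
        top[-1] = candidate
        if candidate != rna_full[i]:  # index i is position i+1, 0-based
            mm_abs.add(i + 1)
    # represent mismatched incorporations by the grouped identity for the template
    template = [rna_complement(rna_full[p - 1]) for p in range(ha, hb + 1)]
    offsets_in_window = set()
    for p in sorted(mm_abs):
        if ha <= p <= hb:
            top[p - ha] = template_mismatch_partner(template[p - ha])
            offsets_in_window.add(hb - p)
    if any(p + 1 in mm_abs for p in mm_abs):
        raise ValueError("two consecutive mismatches are not modeled")

    top_s = "".join(top)
    bottom_s = "".join(template)
    dG_hyb = duplex_dG(tables, top_s, bottom_s, frozenset(offsets_in_window),
                       DuplexClass.RNA_DNA_WC)

    dna_top = coding_seq[ma - 1:mb]
    dna_bottom = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in dna_top)
    # opening cost: minus the (negative) formation energy of the melted window
    dG_open = -duplex_dG(tables, dna_top, dna_bottom, frozenset(), DuplexClass.DNA_DNA)

    return BubbleState(
        template_pos=i, substate=substate, transcript_3prime=top_s,
        mismatch_offsets=frozenset(mismatch_offsets),
        dG_dna_dna=dG_open, dG_rna_dna=dG_hyb, dG_pol=dG_pol)
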