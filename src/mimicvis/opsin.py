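"""SWS1 opsin spectral-tuning classification (UVS vs VS).

Diurnal birds fall into ultraviolet-sensitive (UVS) and violet-sensitive
(VS) classes depending on their short-wavelength-sensitive type 1 (SWS1)
pigment. The shift is governed by a handful of amino-acid replacements
inside the 11-residue window spanning alignment sites 84-94 (bovine
rhodopsin numbering), with sites 86 and 90 doing the heavy lifting:
cysteine at site 90 or phenylalanine at site 86 yields a UV-shifted
pigment, anything else a violet-shifted one. Site 93 is carried in the
data model for completeness but does not enter the default rule.

The module translates short SWS1 gene fragments, locates the tuning
window, and calls UVS/VS per record. The eight predator windows used in
the source analysis ship as a FASTA fixture (``data/sws1_windows.fasta``)
with their expected calls.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio.Seq import Seq

from . import io as _io
from .errors import AlignmentError, FormatError, TranslationError

__all__ = [
    "OpsinSequenceRecord",
    "TuningWindow",
    "VisualTypeCall",
    "translate_fragment",
    "extract_window",
    "classify_sws1",
    "classify_fasta",
    "packaged_fixture_path",
    "WINDOW_FIRST_SITE",
    "WINDOW_LENGTH",
]

WINDOW_FIRST_SITE = 84
WINDOW_LENGTH = 11
KEY_SITES = (86, 90, 93)
_DNA_CHARS = set("ACGTUN")
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# Per-position consensus of known SWS1 windows, used as a motif anchor for
# full-length inputs where no explicit offset is supplied.
_CONSENSUS = ["FL", "IM", "FSC", "C", "VSI", "F", "SC", "VI", "F", "T", "V"]


@dataclass(frozen=True)
class OpsinSequenceRecord:
    species: str
    sequence: str
    common_name: str = ""
    alphabet: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("-", "")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FormatError(f"{self.species}: empty sequence")
        if self.alphabet not in ("dna", "protein"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "dna" and not set(seq) <= _DNA_CHARS:
            raise FormatError(
                f"{self.species}: non-nucleotide characters in a dna record")

    @classmethod
    def from_sequence(cls, species: str, sequence: str,
                      common_name: str = "") -> "OpsinSequenceRecord":
        """Build a record, inferring the alphabet from the characters."""
        alphabet = "dna" if set(sequence.upper()) <= _DNA_CHARS else "protein"
        return cls(species=species, sequence=sequence,
                   common_name=common_name, alphabet=alphabet)


@dataclass(frozen=True)
class TuningWindow:
    """The 11 residues at alignment sites 84-94."""

    residues: str
    first_site: int = WINDOW_FIRST_SITE

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise AlignmentError(
                f"tuning window must be {WINDOW_LENGTH} residues, "
                f"got {len(self.residues)}")

    def site(self, position: int) -> str:
        idx = position - self.first_site
        if not 0 <= idx < WINDOW_LENGTH:
            raise AlignmentError(f"site {position} outside the window")
        return self.residues[idx]

    @property
    def key_sites(self) -> dict[int, str]:
        return {p: self.site(p) for p in KEY_SITES}


@dataclass(frozen=True)
class VisualTypeCall:
    species: str
    type: str  # "UVS" | "VS" | "unknown"
    rule_fired: str
    window: TuningWindow | None = None


def translate_fragment(rec: OpsinSequenceRecord, frame: int | str = "auto") -> str:
    """Translate a nucleotide fragment with the standard code.

    Protein records pass through unchanged. ``frame="auto"`` picks the
    reading frame whose translation contains no internal stop codon and
    raises :class:`TranslationError` if every frame has one.
    """
    if rec.alphabet == "protein":
        return rec.sequence
    seq = rec.sequence.replace("U", "T")
    frames = [0, 1, 2] if frame == "auto" else [int(frame)]
    last_err = None
    for fr in frames:
        sub = seq[fr:]
        sub = sub[: len(sub) - len(sub) % 3]
        if len(sub) < 3:
            last_err = TranslationError(
                f"{rec.species}: fragment too short in frame {fr}")
            continue
        prot = str(Seq(sub).translate())
        if "*" in prot:
            last_err = TranslationError(
                f"{rec.species}: stop codon in frame {fr}")
            continue
        return prot
    raise TranslationError(
        f"{rec.species}: no open reading frame without stop codons"
    ) from last_err


def _motif_offset(protein: str) -> int:
    """Best-scoring placement of the SWS1 window consensus in a protein."""
    best_score, best_off = -1, None
    for off in range(len(protein) - WINDOW_LENGTH + 1):
        win = protein[off:off + WINDOW_LENGTH]
        score = sum(aa in allowed for aa, allowed in zip(win, _CONSENSUS))
        if score > best_score:
            best_score, best_off = score, off
    if best_off is None or best_score < 7:
        raise AlignmentError(
            "spectral-tuning window not locatable by motif anchoring "
            f"(best consensus score {best_score}/11)")
    return best_off


def extract_window(protein: str, offset: int | None = None) -> TuningWindow:
    """Extract the 11-residue tuning window (sites 84-94) from a protein.

    With ``offset`` given, the window starts at that 0-based position;
    otherwise an exact-length input is taken verbatim and longer inputs
    are anchored against a consensus motif.
    """
    protein = protein.upper()
    if len(protein) < WINDOW_LENGTH:
        raise AlignmentError(
            f"protein of length {len(protein)} is shorter than the "
            f"{WINDOW_LENGTH}-residue window")
    if offset is None:
        offset = 0 if len(protein) == WINDOW_LENGTH else _motif_offset(protein)
    if offset < 0 or offset + WINDOW_LENGTH > len(protein):
        raise AlignmentError(
            f"offset {offset} places the window outside the protein")
    window = protein[offset:offset + WINDOW_LENGTH]
    if "X" in window or "*" in window:
        raise AlignmentError(
            f"ambiguous or stop characters inside the tuning window: {window}")
    return TuningWindow(residues=window)


def classify_sws1(w: TuningWindow, species: str = "") -> VisualTypeCall:
    """Call UVS vs VS from the tuning window.

    Rule: UVS iff cysteine at site 90 or phenylalanine at site 86;
    otherwise VS. Non-standard residues at the key sites yield an
    ``unknown`` call with a warning rather than an error.
    """
    s86, s90 = w.site(86), w.site(90)
    if s86 not in _AA20 or s90 not in _AA20:
        warnings.warn(
            f"{species or 'record'}: non-standard residue at a key tuning "
            f"site (86={s86}, 90={s90}); type call is 'unknown'", stacklevel=2)
        return VisualTypeCall(species=species, type="unknown",
                              rule_fired="non-standard key residue", window=w)
    if s90 == "C":
        return VisualTypeCall(species=species, type="UVS",
                              rule_fired="C90 (cysteine at site 90)", window=w)
    if s86 == "F":
        return VisualTypeCall(species=species, type="UVS",
                              rule_fired="F86 (phenylalanine at site 86)", window=w)
    return VisualTypeCall(species=species, type="VS",
                          rule_fired=f"neither C90 nor F86 (86={s86}, 90={s90})",
                          window=w)


def classify_fasta(path: str | Path, frame: int | str = "auto",
                   offset: int | None = None) -> list[VisualTypeCall]:
    """Classify every record of a FASTA file (DNA or protein).

    Returns one call per record in file order; an empty file yields an
    empty list with a warning.
    """
    records = _io.read_fasta(path)
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
        return []
    calls = []
    for name, desc, seq in records:
        rec = OpsinSequenceRecord.from_sequence(name, seq, common_name=desc)
        protein = translate_fragment(rec, frame=frame)
        window = extract_window(protein, offset=offset)
        calls.append(classify_sws1(window, species=name))
    return calls


def summarize_calls(calls: list[VisualTypeCall]) -> dict[str, int]:
    """Counts of calls by visual type."""
    return dict(Counter(c.type for c in calls))


def packaged_fixture_path() -> Path:
    """Path to the packaged FASTA of the eight predator SWS1 windows."""
    return Path(str(resources.files("mimicvis.data").joinpath("sws1_windows.fasta")))
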