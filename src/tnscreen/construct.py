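"""Construct specifications and barcode/host extraction from reads.

In an RB-TnSeq read the random barcode sits immediately upstream of a fixed
construct sequence (the transposon end, e.g. the Tn5 mosaic end).  That fixed
sequence is used as an anchor: once located in a read, the barcode is the
``barcode_length`` bases preceding it (optionally separated by a fixed-length
spacer), and everything downstream of the anchor is host genomic sequence
from the insertion junction.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from typing import IO, Iterator, Optional, Union

__all__ = [
    "ConstructSpec",
    "Extraction",
    "parse_construct_spec",
    "extract_from_read",
    "iter_fastq",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_SPEC_RE = re.compile(r"^B(?P<bc>\d+)(?:N(?P<spacer>\d+))?(?P<end>[ACGTacgt]+)$")

#: Tn5 mosaic end, the default anchor sequence.
TN5_END_SEQUENCE = "GTGTATAAGAGACAG"

DEFAULT_BARCODE_LENGTH = 17
DEFAULT_MAX_ANCHOR_MISMATCHES = 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConstructSpecError(ValueError):
    """Malformed or invalid construct specification."""


@dataclass(frozen=True)
class ConstructSpec:
    """How to recognise the barcode and host sequence inside a read.

    Parameters
    ----------
    barcode_length : int
        Length of the random barcode in bp (default 17, the Tn5 setup).
    end_sequence : str
        Fixed construct/transposon end used as the anchor; >= 10 bp.
    max_anchor_mismatches : int
        Substitution budget when locating the anchor (no indels).
    spacer_length : int
        Fixed number of bases between barcode and anchor (default 0).
    """

    barcode_length: int = DEFAULT_BARCODE_LENGTH
    end_sequence: str = TN5_END_SEQUENCE
    max_anchor_mismatches: int = DEFAULT_MAX_ANCHOR_MISMATCHES
    spacer_length: int = 0

    def __post_init__(self) -> None:
        if self.barcode_length < 1:
            raise ConstructSpecError("barcode_length must be >= 1")
        if len(self.end_sequence) < 10:
            raise ConstructSpecError(
                f"end_sequence must be at least 10 bp, got {len(self.end_sequence)}"
            )
        if not re.fullmatch(r"[ACGT]+", self.end_sequence):
            raise ConstructSpecError(
                "end_sequence must contain only A, C, G, T: "
                f"{self.end_sequence!r}"
            )
        if self.max_anchor_mismatches >= len(self.end_sequence) / 3:
            raise ConstructSpecError(
                "max_anchor_mismatches must be below end_sequence length / 3"
            )
        if self.spacer_length < 0:
            raise ConstructSpecError("spacer_length must be >= 0")


@dataclass(frozen=True)
class Extraction:
    """Result of scanning one read: barcode and (optionally) host sequence."""

    read_id: str
    barcode: Optional[str] = None
    host: str = ""
    anchor_start: Optional[int] = None


def parse_construct_spec(text: str) -> ConstructSpec:
    """Parse a compact construct grammar ``B<len>[N<spacer>]<end-sequence>``.

    Examples: ``B17GTGTATAAGAGACAG`` (17-bp barcode directly upstream of the
    Tn5 mosaic end), ``B17N13GTGTATAAGAGACAG`` (13-bp spacer in between).
    """
    m = _SPEC_RE.match(text.strip())
    if m is None:
        # pinpoint the offending token for the error message
        rest = text.strip()
        if not rest.startswith("B"):
            raise ConstructSpecError(
                f"construct spec must start with 'B<int>', got {rest[:8]!r}"
            )
        body = rest[1:]
        if not body or not body[0].isdigit():
            raise ConstructSpecError(
                f"expected barcode length after 'B', got {body[:8]!r}"
            )
        tail = body.lstrip("0123456789")
        if tail.startswith("N"):
            tail2 = tail[1:].lstrip("0123456789")
            raise ConstructSpecError(
                f"invalid end sequence token {tail2[:12]!r} (must be A/C/G/T)"
            )
        raise ConstructSpecError(
            f"invalid end sequence token {tail[:12]!r} (must be A/C/G/T)"
        )
    return ConstructSpec(
        barcode_length=int(m.group("bc")),
        spacer_length=int(m.group("spacer") or 0),
        end_sequence=m.group("end").upper(),
    )


def _find_anchor(seq: str, anchor: str, max_mismatches: int) -> Optional[int]:
    """Leftmost offset of `anchor` in `seq` with <= max_mismatches substitutions.

    Exact-match fast path first: str.find locates the leftmost exact hit, and
    only offsets left of it need the mismatch scan.
    """
    la = len(anchor)
    n = len(seq) - la
    if n < 0:
        return None
    exact = seq.find(anchor)
    limit = exact if exact >= 0 else n
    for off in range(limit):
        mism = 0
        for a, b in zip(anchor, seq[off : off + la]):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return off
    return exact if exact >= 0 else None


def extract_from_read(
    read_id: str,
    sequence: str,
    spec: ConstructSpec,
    want_host: bool = False,
) -> Extraction:
    """Locate the construct anchor in a read and pull out barcode and host.

    The anchor is searched with a substitution-only budget, leftmost match
    first, on the forward sequence and then on the reverse complement.  The
    barcode is the ``barcode_length`` bases ending ``spacer_length`` bases
    before the anchor; absent if the anchor is missing or there is not enough
    sequence upstream of it.  Host (mapping mode) is everything downstream of
    the anchor match.
    """
    seq = sequence.upper()
    for oriented in (seq, reverse_complement(seq)):
        off = _find_anchor(oriented, spec.end_sequence, spec.max_anchor_mismatches)
        if off is None:
            continue
        bc_end = off - spec.spacer_length
        bc_start = bc_end - spec.barcode_length
        if bc_start < 0:
            return Extraction(read_id=read_id, anchor_start=off)
        barcode = oriented[bc_start:bc_end]
        host = oriented[off + len(spec.end_sequence) :] if want_host else ""
        return Extraction(
            read_id=read_id, barcode=barcode, host=host, anchor_start=off
        )
    return Extraction(read_id=read_id)


def iter_fastq(path_or_handle: Union[str, IO[str]]) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file, transparently gunzipping.

    Biopython's SimpleFastqParser is used for speed; qualities are discarded
    because extraction is sequence-only.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    if isinstance(path_or_handle, str):
        opener = gzip.open if path_or_handle.endswith(".gz") else open
        with opener(path_or_handle, "rt") as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq
    else:
        for title, seq, _qual in FastqGeneralIterator(path_or_handle):
            yield title.split()[0], seq
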