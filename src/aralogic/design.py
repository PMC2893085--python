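"""In-silico reporter design: consensus operators and degenerate primers.

A transcription-factor reporter is built by placing the factor's operator
immediately downstream of a constitutive sigma-70 promoter, so that factor
binding represses an otherwise constant signal.  Operators are designed as
IUPAC consensus strings over aligned binding sites; degenerate positions
(N, M, ...) expand into a library of variants whose size this module
accounts for exactly.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "SYNRNAP_SIGMA70",
    "AlignedSites",
    "ReporterConstruct",
    "iupac_consensus",
    "count_degenerate_variants",
    "build_reporter_sequence",
    "load_primers",
]

#: The medium-strength constitutive sigma-70 promoter used as the reporter
#: scaffold (47 nt).
SYNRNAP_SIGMA70 = "AATAATTCTTGAAATTTATGCTTCCGGCTCGTATTTTACGTGCAATT"

_IUPAC = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}
_CODE_FOR = {bases: code for code, bases in _IUPAC.items()}


@dataclass(frozen=True)
class AlignedSites:
    """An alignment of binding-site sequences (equal length, A/C/G/T/-)."""

    sequences: tuple

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if len(seqs) < 2:
            raise ValueError("need at least two aligned sequences")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("aligned sequences must have equal length")
        allowed = set("ACGT-")
        for s in seqs:
            bad = set(s) - allowed
            if bad:
                raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class ReporterConstruct:
    """A reporter: constitutive promoter with the operator directly 3' of it.

    ``junction`` is the 1-based coordinate of the first operator base in the
    full sequence; ``n_variants`` counts the library members encoded by
    degenerate positions in the operator.
    """

    promoter_seq: str
    operator_seq: str
    full_seq: str
    junction: int
    n_variants: int

    def to_record(self) -> dict:
        return {
            "promoter_seq": self.promoter_seq,
            "operator_seq": self.operator_seq,
            "full_seq": self.full_seq,
            "junction_1based": self.junction,
            "n_variants": self.n_variants,
            "coordinates": "1-based inclusive",
        }


def _validate_iupac(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in _IUPAC:
            raise ValueError(f"invalid character {ch!r} at position {i} of {what}")
    return seq


def iupac_consensus(sites: AlignedSites, purity_threshold: float = 0.0) -> str:
    """Minimal IUPAC consensus of an alignment, column by column.

    A base is covered in a column when its frequency (among non-gap
    characters) exceeds ``purity_threshold``; the column's code is the
    minimal IUPAC symbol covering all such bases.  The default threshold 0
    covers every observed base; e.g. 0.5 gives a majority consensus.  Gaps
    are ignored for code selection; an all-gap column is an error.
    """
    if not 0.0 <= purity_threshold < 1.0:
        raise ValueError("purity_threshold must lie in [0, 1)")
    out = []
    for col in range(sites.length):
        column = [s[col] for s in sites.sequences if s[col] != "-"]
        if not column:
            raise ValueError(f"column {col + 1} is all gaps")
        n = len(column)
        covered = frozenset(
            b for b in "ACGT" if column.count(b) / n > purity_threshold
        )
        if not covered:
            # threshold above every base's frequency: fall back to the mode
            top = max("ACGT", key=column.count)
            covered = frozenset(top)
        out.append(_CODE_FOR[covered])
    return "".join(out)


def count_degenerate_variants(seq: str) -> int:
    """Number of concrete DNA variants an IUPAC string expands into.

    The product over positions of each code's base multiplicity; a plain
    A/C/G/T string counts 1.
    """
    seq = _validate_iupac(seq, "IUPAC sequence")
    n = 1
    for ch in seq:
        n *= len(_IUPAC[ch])
    return n


def build_reporter_sequence(promoter: str, operator: str) -> ReporterConstruct:
    """Assemble a reporter: operator immediately downstream of the promoter."""
    if not promoter or not operator:
        raise ValueError("promoter and operator must be non-empty")
    promoter = _validate_iupac(promoter, "promoter")
    operator = _validate_iupac(operator, "operator")
    return ReporterConstruct(
        promoter_seq=promoter,
        operator_seq=operator,
        full_seq=promoter + operator,
        junction=len(promoter) + 1,
        n_variants=count_degenerate_variants(operator),
    )


def load_primers() -> dict:
    """The study's cloning and reporter-design primers, name -> sequence."""
    ref = resources.files("aralogic").joinpath("data/primers.fasta")
    with ref.open("r") as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
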