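"""Nucleotide alignments over the alphabet {A, C, G, T, -}.

A thin immutable container keyed by taxon name.  All sequences must
have equal length; gaps ('-') are carried through and treated as
missing data by the inference code.  FASTA I/O goes through Biopython.
"""

from __future__ import annotations

import io
import os
from collections.abc import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT-"
GAP_CODE = 4
_CODE = {c: i for i, c in enumerate(ALPHABET)}

__all__ = ["Alignment", "ALPHABET", "GAP_CODE"]


class Alignment:
    """Equal-length nucleotide sequences keyed by unique taxon names."""

    __slots__ = ("_seqs", "_taxa", "_length")

    def __init__(self, sequences: Mapping[str, str]):
        seqs = {}
        length = None
        for name, seq in sequences.items():
            if not name:
                raise ValueError("taxon names must be non-empty")
            seq = str(seq).upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"sequence for {name!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise ValueError(f"sequence for {name!r} contains invalid characters {sorted(bad)}")
            seqs[name] = seq
        if not seqs:
            raise ValueError("alignment must contain at least one sequence")
        self._seqs = seqs
        self._taxa = tuple(seqs)
        self._length = length

    @property
    def taxa(self) -> tuple[str, ...]:
        """Taxon names in insertion order (the canonical order)."""
        return self._taxa

    @property
    def n_taxa(self) -> int:
        return len(self._taxa)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return self._length

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"<Alignment {self.n_taxa} taxa x {self.length} columns>"

    def items(self):
        return self._seqs.items()

    def drop(self, *names: str) -> "Alignment":
        missing = [n for n in names if n not in self._seqs]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        return Alignment({n: s for n, s in self._seqs.items() if n not in names})

    def subset(self, names) -> "Alignment":
        return Alignment({n: self._seqs[n] for n in names})

    def replace(self, name: str, seq: str) -> "Alignment":
        if name not in self._seqs:
            raise KeyError(f"taxon not in alignment: {name}")
        out = dict(self._seqs)
        out[name] = seq
        return Alignment(out)

    def codes(self, taxa=None) -> np.ndarray:
        """Integer matrix (n_taxa x length): A,C,G,T,- -> 0..4."""
        taxa = self._taxa if taxa is None else tuple(taxa)
        mat = np.empty((len(taxa), self._length), dtype=np.uint8)
        for i, name in enumerate(taxa):
            mat[i] = np.frombuffer(self._seqs[name].encode("ascii"), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for ch, code in _CODE.items():
            lut[ord(ch)] = code
        return lut[mat]

    # -- FASTA -------------------------------------------------------------------

    def to_fasta(self, path=None) -> str | None:
        """Write gapped FASTA (60-column wrapped); returns the text if no path."""
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        ]
        if path is None:
            handle = io.StringIO()
            SeqIO.write(records, handle, "fasta")
            return handle.getvalue()
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        return None

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        """Read from a path, an open handle, or a FASTA-formatted string."""
        if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith(">"):
            with open(source) as fh:
                records = list(SeqIO.parse(fh, "fasta"))
        elif isinstance(source, str):
            records = list(SeqIO.parse(io.StringIO(source), "fasta"))
        else:
            records = list(SeqIO.parse(source, "fasta"))
        if not records:
            raise ValueError("no sequences found in FASTA input")
        seqs = {}
        for rec in records:
            if rec.id in seqs:
                raise ValueError(f"duplicate taxon in FASTA: {rec.id}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs)
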