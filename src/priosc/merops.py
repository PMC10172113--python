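"""Semi-tryptic proteolytic-product generation from protease cleavage annotations.

Protease cleavage annotations (MEROPS-style: protein, enzyme, P1 residue
position) describe scissile bonds between the P1 and P1' residues.  Cleavage
records consistent with trypsin itself (K or R at P1) carry no extra
information for a tryptic search and are removed.  For every remaining
annotated site, the parent sequence is split between P1 and P1', and each half
is digested in silico with trypsin; the tryptic fragment abutting the cleavage
site on each side is emitted as a semi-tryptic peptide entry — the fragment
ending at the cut carries the neo-C terminus, the fragment starting just after
the cut carries the neo-N terminus.  Fragments shorter than ``min_len``
residues (default 6) are suppressed.  Emitted fragments are appended to the
FASTA as separate entries with annotated headers; original entries are
preserved unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CleavageRecord",
    "NeoFragment",
    "read_cleavage_records",
    "filter_tryptic_cleavages",
    "tryptic_sites",
    "augment_fasta",
    "read_fasta",
    "write_fasta",
]

TRYPTIC_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class CleavageRecord:
    """One annotated protease cleavage site (cut between P1 and P1')."""

    protein_id: str
    enzyme: str
    p1_position: int  # 1-based residue index of the P1 residue
    p1_residue: str

    def validate(self, sequence: str) -> None:
        if not (1 <= self.p1_position < len(sequence)):
            raise ValueError(
                f"{self.protein_id}: P1 position {self.p1_position} outside 1..{len(sequence) - 1}"
            )
        actual = sequence[self.p1_position - 1]
        if actual != self.p1_residue:
            raise ValueError(
                f"{self.protein_id}: annotated P1 {self.p1_residue!r} != sequence residue {actual!r}"
            )


@dataclass(frozen=True)
class NeoFragment:
    """Semi-tryptic peptide with one protease-generated terminus."""

    parent_protein_id: str
    sequence: str
    terminus_kind: str  # "neo_C" | "neo_N"
    cleavage_enzyme: str
    cleavage_position: int
    header_annotation: str


def read_cleavage_records(path) -> list[CleavageRecord]:
    """Cleavage records from TSV (protein_id, enzyme, p1_position[, p1_residue])."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples():
        records.append(
            CleavageRecord(
                protein_id=str(row.protein_id),
                enzyme=str(row.enzyme),
                p1_position=int(row.p1_position),
                p1_residue=str(getattr(row, "p1_residue", "")) or "",
            )
        )
    return records


def filter_tryptic_cleavages(
    records: Iterable[CleavageRecord],
    sequences: Mapping[str, str] | None = None,
) -> list[CleavageRecord]:
    """Remove cleavage records whose P1 residue is K or R (trypsin-consistent).

    When ``sequences`` is given, records referencing unknown proteins are
    dropped with a warning, and empty P1 annotations are resolved from the
    sequence.  Order is preserved.
    """
    kept: list[CleavageRecord] = []
    for rec in records:
        if sequences is not None:
            seq = sequences.get(rec.protein_id)
            if seq is None:
                warnings.warn(f"cleavage record references unknown protein {rec.protein_id!r}; dropped")
                continue
            if not rec.p1_residue:
                rec = CleavageRecord(rec.protein_id, rec.enzyme, rec.p1_position, seq[rec.p1_position - 1])
            rec.validate(seq)
        if rec.p1_residue in TRYPTIC_RESIDUES:
            continue
        kept.append(rec)
    return kept


def tryptic_sites(sequence: str, block_proline: bool = False) -> list[int]:
    """1-based positions after which trypsin cuts (K/R; optionally not before P)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in TRYPTIC_RESIDUES:
            if block_proline and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def _neo_fragments(
    sequence: str, rec: CleavageRecord, min_len: int, block_proline: bool
) -> list[NeoFragment]:
    cut = rec.p1_position  # cut between cut and cut+1 (1-based)
    n_half = sequence[:cut]
    c_half = sequence[cut:]
    fragments: list[NeoFragment] = []

    # neo-C fragment: from the residue after the last tryptic site in the
    # N-terminal half through the cut.
    sites_n = [s for s in tryptic_sites(n_half, block_proline) if s < cut]
    start = sites_n[-1] if sites_n else 0
    frag_c = n_half[start:]
    if len(frag_c) >= min_len:
        fragments.append(
            NeoFragment(
                parent_protein_id=rec.protein_id,
                sequence=frag_c,
                terminus_kind="neo_C",
                cleavage_enzyme=rec.enzyme,
                cleavage_position=cut,
                header_annotation=f"{rec.protein_id}|MEROPS|{rec.enzyme}|pos{cut}|neo_C",
            )
        )

    # neo-N fragment: from the cut to the first tryptic site of the C-terminal
    # half (or the protein terminus when no site exists).
    sites_c = tryptic_sites(c_half, block_proline)
    end = sites_c[0] if sites_c else len(c_half)
    frag_n = c_half[:end]
    if len(frag_n) >= min_len:
        fragments.append(
            NeoFragment(
                parent_protein_id=rec.protein_id,
                sequence=frag_n,
                terminus_kind="neo_N",
                cleavage_enzyme=rec.enzyme,
                cleavage_position=cut,
                header_annotation=f"{rec.protein_id}|MEROPS|{rec.enzyme}|pos{cut}|neo_N",
            )
        )
    return fragments


def augment_fasta(
    fasta: Mapping[str, str] | Iterable[SeqRecord],
    records: Iterable[CleavageRecord],
    min_len: int = 6,
    block_proline: bool = False,
) -> tuple[list[NeoFragment], list[SeqRecord]]:
    """Append semi-tryptic cleavage-product entries to a protein FASTA.

    ``records`` should already have passed :func:`filter_tryptic_cleavages`.
    Returns the emitted fragments and the combined record list (originals
    unchanged, fragments appended with annotated headers).
    """
    if isinstance(fasta, Mapping):
        originals = [SeqRecord(Seq(s), id=pid, description="") for pid, s in fasta.items()]
        seqs = dict(fasta)
    else:
        originals = list(fasta)
        seqs = {r.id: str(r.seq) for r in originals}

    fragments: list[NeoFragment] = []
    for rec in records:
        seq = seqs.get(rec.protein_id)
        if seq is None:
            warnings.warn(f"cleavage record references unknown protein {rec.protein_id!r}; skipped")
            continue
        rec.validate(seq)
        fragments.extend(_neo_fragments(seq, rec, min_len, block_proline))

    combined = list(originals)
    for frag in fragments:
        combined.append(SeqRecord(Seq(frag.sequence), id=frag.header_annotation, description=""))
    return fragments, combined


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fasta"))


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), path, "fasta")
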