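"""Extracellular-gate conservation pipeline for full-size ABCG sequences.

Screens protein sequence panels for full-size ABCG/PDR family signatures
(length window plus the four PDR motifs, with X as a single-residue
wildcard), maps reference gate positions through alignments, tabulates
per-taxon amino-acid occurrence at the mapped positions, computes
sequence-logo information content and calls consensus motifs such as the
gate pattern "G F x x S/P R/K x x".

FASTA headers use the dialect ``>id|taxon``; a header without a pipe gets
taxon "unknown". Alignment gaps are ``-`` and are tracked as a 21st
category in occurrence tables but excluded from information content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "SeqRecord",
    "FilterSpec",
    "MotifPattern",
    "GateAnnotation",
    "DEFAULT_GATE_ANNOTATION",
    "MSA",
    "ResidueFrequencyTable",
    "read_fasta",
    "write_fasta",
    "find_motif",
    "filter_full_size",
    "align_global",
    "ref_positions_to_columns",
    "columns_to_ref_positions",
    "extract_gate_residues",
    "occurrence_by_taxon",
    "information_content",
    "consensus_motif",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: plant PDR signature motifs (X = any single residue)
PDR_MOTIFS = ("LLXGPP", "GLXSS", "GLDARXAAXVMR", "VCTIHQP")


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence with an id and a family (taxon) tag."""

    id: str
    taxon: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class MotifPattern:
    """Exact-match motif over amino-acid letters with X wildcards."""

    pattern: str

    def __post_init__(self):
        if len(self.pattern) < 3:
            raise ValueError("motif must have length >= 3")
        if not re.fullmatch(f"[{AMINO_ACIDS}X]+", self.pattern.upper()):
            raise ValueError(f"invalid motif pattern: {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())


@dataclass(frozen=True)
class FilterSpec:
    """Full-size ABCG screen: length window + required signature motifs."""

    min_len: int = 950
    max_len: int = 1800
    motifs: Tuple[MotifPattern, ...] = tuple(MotifPattern(m) for m in PDR_MOTIFS)

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.motifs:
            raise ValueError("at least one motif required")


@dataclass(frozen=True)
class GateAnnotation:
    """Reference gate positions and the four helix segments (1-based)."""

    reference_id: str = "AtABCG36"
    gate_positions: Tuple[int, ...] = (703, 704, 1374, 1375)
    helix_segments: Mapping[Tuple[int, int], str] = field(default_factory=lambda: {
        (582, 597): "FGMIINMFNGFAEMAM",
        (685, 700): "IANTGGALTLLLVFLL",
        (1250, 1265): "LYAAIIFVGINNCSTV",
        (1356, 1371): "VASIFASAFYGIFNLF",
    })

    def __post_init__(self):
        for (a, b), seg in self.helix_segments.items():
            if len(seg) != b - a + 1:
                raise ValueError(f"segment {a}-{b} length mismatch")

    def segment_residue(self, position: int) -> str:
        """Residue at a reference position inside one of the segments."""
        for (a, b), seg in self.helix_segments.items():
            if a <= position <= b:
                return seg[position - a]
        raise KeyError(f"position {position} outside the annotated segments")


DEFAULT_GATE_ANNOTATION = GateAnnotation()


# ---------------------------------------------------------------------------
# FASTA I/O

def _parse_header(header: str) -> Tuple[str, str]:
    if "|" in header:
        rid, taxon = header.split("|", 1)
        return rid, taxon or "unknown"
    return header, "unknown"


def read_fasta(path) -> List[SeqRecord]:
    """Read a FASTA file of ``>id|taxon`` records (uppercased, '*' stripped)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, taxon = _parse_header(rec.id)
        if rid in seen:
            raise ValueError(f"duplicate sequence id: {rid}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace("*", "")
        records.append(SeqRecord(id=rid, taxon=taxon, residues=seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records in the ``>id|taxon`` dialect (pipe omitted for 'unknown')."""
    bio = []
    for r in records:
        name = r.id if r.taxon == "unknown" else f"{r.id}|{r.taxon}"
        bio.append(BioSeqRecord(Seq(r.residues), id=name, description=""))
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Motif screening

def find_motif(seq: str, pattern: MotifPattern | str) -> List[int]:
    """1-based start positions of all (possibly overlapping) matches."""
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    rx = re.compile("(?=" + pattern.pattern.replace("X", ".") + ")")
    return [m.start() + 1 for m in rx.finditer(seq.upper())]


def filter_full_size(records: Sequence[SeqRecord],
                     spec: FilterSpec | None = None):
    """Partition records into (kept, rejected) by the full-size ABCG screen.

    A record is kept iff its length is within [min_len, max_len]
    (inclusive) and every signature motif matches at least once. Rejections
    carry the first failing criterion. Idempotent on its own kept output.
    """
    spec = spec or FilterSpec()
    kept: List[SeqRecord] = []
    rejected: List[Tuple[SeqRecord, str]] = []
    for r in records:
        if not spec.min_len <= len(r) <= spec.max_len:
            rejected.append((r, "length"))
            continue
        for m in spec.motifs:
            if not find_motif(r.residues, m):
                rejected.append((r, f"motif {m.pattern}"))
                break
        else:
            kept.append(r)
    return kept, rejected


# ---------------------------------------------------------------------------
# Alignment and position mapping

def align_global(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = -10.0, gap_extend: float = -0.5):
    """Optimal global alignment with affine gaps.

    Affine convention: a gap of length L costs ``gap_open + L * gap_extend``
    (the first gap position costs open + extend). End gaps are penalized
    like internal ones. Returns (aligned_a, aligned_b, score).
    """
    mat = substitution_matrices.load(matrix)
    for s, name in ((a, "first"), (b, "second")):
        for ch in set(s):
            if ch not in mat.alphabet:
                raise ValueError(f"letter {ch!r} in {name} sequence absent from {matrix}")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = mat
    aligner.mode = "global"
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    if not a or not b:
        # degenerate: all-gap alignment, one gap run per missing side
        score = 0.0
        for s in (a, b):
            if not s:
                continue
            score += gap_open + gap_extend * len(s)
        return "-" * len(b) if not a else a, "-" * len(a) if not b else b, score
    aln = aligner.align(a, b)
    best = aln[0]
    # rebuild the gapped strings from coordinates (format-stable across versions)
    aligned_a, aligned_b = _expand_alignment(a, b, best.coordinates)
    return aligned_a, aligned_b, float(best.score)


def _expand_alignment(a: str, b: str, coords: np.ndarray) -> Tuple[str, str]:
    ra, rb = [], []
    for k in range(coords.shape[1] - 1):
        a0, a1 = coords[0, k], coords[0, k + 1]
        b0, b1 = coords[1, k], coords[1, k + 1]
        if a1 > a0 and b1 > b0:
            ra.append(a[a0:a1])
            rb.append(b[b0:b1])
        elif a1 > a0:
            ra.append(a[a0:a1])
            rb.append("-" * (a1 - a0))
        else:
            ra.append("-" * (b1 - b0))
            rb.append(b[b0:b1])
    return "".join(ra), "".join(rb)


@dataclass
class MSA:
    """Aligned records of equal length with a designated reference row."""

    records: List[SeqRecord]
    reference_id: str

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty alignment")
        n = len(self.records[0].residues)
        if any(len(r.residues) != n for r in self.records):
            raise ValueError("aligned records must have equal length")
        if self.reference_id not in {r.id for r in self.records}:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def reference_row(self) -> str:
        return next(r.residues for r in self.records if r.id == self.reference_id)

    def __len__(self):
        return len(self.records)


def ref_positions_to_columns(msa: MSA, positions: Iterable[int]) -> Dict[int, int]:
    """Map 1-based reference positions to 1-based alignment columns.

    The k-th non-gap character of the reference row sits in the returned
    column; the mapping is bijective on the reference's non-gap positions
    (see :func:`columns_to_ref_positions` for the inverse).
    """
    row = msa.reference_row
    cols = [i + 1 for i, c in enumerate(row) if c != "-"]
    n_ref = len(cols)
    out = {}
    for p in positions:
        if not 1 <= p <= n_ref:
            raise ValueError(f"position {p} beyond reference length {n_ref}")
        out[p] = cols[p - 1]
    return out


def columns_to_ref_positions(msa: MSA, columns: Iterable[int]) -> Dict[int, int]:
    """Inverse of :func:`ref_positions_to_columns` (reference gap columns error)."""
    row = msa.reference_row
    col_to_pos = {}
    p = 0
    for i, c in enumerate(row):
        if c != "-":
            p += 1
            col_to_pos[i + 1] = p
    out = {}
    for c in columns:
        if c not in col_to_pos:
            raise ValueError(f"column {c} is a gap in the reference")
        out[c] = col_to_pos[c]
    return out


def extract_gate_residues(record, annotation: GateAnnotation | None = None,
                          via: str = "pairwise", msa: MSA | None = None,
                          reference: SeqRecord | None = None,
                          positions: Iterable[int] | None = None) -> Dict[int, str]:
    """Residues of a record at the reference gate positions.

    via="msa-columns": ``record`` must be an aligned row of ``msa``;
    positions map through the reference row of the alignment.
    via="pairwise": ``record`` is an unaligned sequence; it is globally
    aligned to ``reference`` and positions map through that alignment.
    Gaps are reported as '-'.
    """
    annotation = annotation or DEFAULT_GATE_ANNOTATION
    positions = list(positions) if positions is not None else list(annotation.gate_positions)
    if via == "msa-columns":
        if msa is None:
            raise ValueError("msa-columns extraction needs the alignment")
        cols = ref_positions_to_columns(msa, positions)
        row = record.residues if isinstance(record, SeqRecord) else str(record)
        return {p: row[c - 1] for p, c in cols.items()}
    if via == "pairwise":
        if reference is None:
            raise ValueError("pairwise extraction needs the reference sequence")
        seq = record.residues if isinstance(record, SeqRecord) else str(record)
        ar, aq = align_global(reference.residues, seq)[:2]
        pair = MSA(records=[SeqRecord("__ref__", "unknown", ar),
                            SeqRecord("__qry__", "unknown", aq)],
                   reference_id="__ref__")
        cols = ref_positions_to_columns(pair, positions)
        return {p: aq[c - 1] for p, c in cols.items()}
    raise ValueError(f"unknown extraction mode: {via!r}")


# ---------------------------------------------------------------------------
# Occurrence tables, logos, consensus

@dataclass
class ResidueFrequencyTable:
    """Per (reference position, taxon) amino-acid counts and fractions."""

    counts: pd.DataFrame  # index (position, taxon), columns = residue letters + '-'

    def fractions(self, position: int, taxon: str) -> Dict[str, float]:
        row = self.counts.loc[(position, taxon)]
        total = row.sum()
        return {k: v / total for k, v in row.items() if v > 0}

    def counts_at(self, position: int, taxon: str) -> Dict[str, int]:
        row = self.counts.loc[(position, taxon)]
        return {k: int(v) for k, v in row.items() if v > 0}


def occurrence_by_taxon(extractions: Sequence[Tuple[str, Mapping[int, str]]]
                        ) -> ResidueFrequencyTable:
    """Tabulate per-taxon residue occurrence at each gate position.

    ``extractions`` holds (taxon, {position: residue-or-gap}) per record.
    Gaps count as their own category; fractions over all categories sum to 1.
    """
    cells: Dict[Tuple[int, str], Dict[str, int]] = {}
    for taxon, mapping in extractions:
        for pos, aa in mapping.items():
            cell = cells.setdefault((pos, taxon), {})
            cell[aa] = cell.get(aa, 0) + 1
    df = pd.DataFrame.from_dict(cells, orient="index").fillna(0).astype(int)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["position", "taxon"])
    return ResidueFrequencyTable(counts=df.sort_index())


def information_content(column_counts: Mapping[str, float],
                        small_sample_correction: bool = False) -> float:
    """Sequence-logo information content of a column, in bits.

    ``R = log2(20) - H`` with ``H`` the Shannon entropy of the observed
    amino-acid distribution; gaps are excluded (an all-gap column is
    undefined and raises). The optional small-sample correction subtracts
    ``(20 - 1) / (2 ln 2 n)``, clipped at zero.
    """
    counts = {aa: c for aa, c in column_counts.items() if aa != "-" and c > 0}
    n = sum(counts.values())
    if n < 1:
        raise ValueError("all-gap column: information content undefined")
    p = np.array(list(counts.values()), dtype=float) / n
    h = float(-(p * np.log2(p)).sum())
    r = np.log2(20.0) - h
    if small_sample_correction:
        r -= (20.0 - 1.0) / (2.0 * np.log(2.0) * n)
    return float(max(r, 0.0))


def consensus_motif(profile: Sequence[Mapping[str, float]],
                    t_single: float = 0.5, t_pair: float = 0.5,
                    t_member: float = 0.2) -> str:
    """Call a consensus token per position of a frequency profile.

    Per position: the top residue if its fraction >= t_single; else
    "A/B" (fractions descending, ties alphabetical) if the top two sum to
    >= t_pair and each reaches t_member; else "x". Tokens are joined by
    spaces, e.g. "G F x x S/P R/K x x".
    """
    for t in (t_single, t_pair, t_member):
        if not 0 < t <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    tokens = []
    for fracs in profile:
        aas = {k: v for k, v in fracs.items() if k != "-"}
        total = sum(aas.values())
        if total <= 0:
            tokens.append("x")
            continue
        items = sorted(aas.items(), key=lambda kv: (-kv[1] / total, kv[0]))
        (a1, f1) = items[0]
        f1 /= total
        if f1 >= t_single:
            tokens.append(a1)
            continue
        if len(items) > 1:
            a2, f2 = items[1]
            f2 /= total
            if f1 + f2 >= t_pair and f1 >= t_member and f2 >= t_member:
                tokens.append(f"{a1}/{a2}")
                continue
        tokens.append("x")
    return " ".join(tokens)
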