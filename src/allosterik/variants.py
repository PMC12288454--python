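"""Alignment-based variant census of a homolog panel against a reference.

Given a FASTA panel of repressor homologs and a reference sequence, this
module filters records to the expected length, calls amino-acid
substitutions from global pairwise alignments, de-duplicates them into
unique variants with carrier lists, and classifies each by domain
(DNA-binding domain, linker, effector-binding/oligomerisation domain).

The default domain boundaries for the 229-residue GntR/FadR-family
repressor studied here are DBD 1–63, linker 64–79, EO 80–229 — the unique
contiguous ranges consistent with the published residue→domain assignments
(positions 3, 15, 19, 24 in the DBD; 71 in the linker; 92, 128, 152, 180,
186, 220, 222 in the EO domain) and the 4/1/7 per-domain variant split.
They are a documented reconstruction, not published boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DomainMap:
    """Ordered, contiguous 1-based domain segments covering the reference."""

    segments: tuple  # ((label, start, end), ...)

    def __post_init__(self):
        segs = tuple(tuple(s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = 0
        for label, start, end in segs:
            if start != prev_end + 1 or end < start:
                raise ValueError(f"domain segments must tile 1..L; bad segment {label} {start}-{end}")
            prev_end = end

    @property
    def length(self) -> int:
        return self.segments[-1][2]

    def classify(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        for label, start, end in self.segments:
            if start <= position <= end:
                return label
        raise AssertionError("unreachable: segments tile the reference")


DEFAULT_DOMAIN_MAP = DomainMap((("DBD", 1, 63), ("linker", 64, 79), ("EO", 80, 229)))


def classify_domain(position: int, domain_map: DomainMap = DEFAULT_DOMAIN_MAP) -> str:
    """Domain label covering a 1-based reference position."""
    return domain_map.classify(position)


@dataclass
class VariantCall:
    position: int
    ref_aa: str
    alt_aa: str
    domain_label: str
    carrier_ids: list

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues are identical")

    @property
    def name(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)


@dataclass
class VariantPanelReport:
    n_sequences_scanned: int
    n_length_filtered: int
    unique_variants: list
    per_domain_counts: dict
    n_carrier_sequences: int
    indels: list = field(default_factory=list)
    low_homology_ids: list = field(default_factory=list)

    @property
    def n_unique(self) -> int:
        return len(self.unique_variants)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant": v.name,
                    "position": v.position,
                    "ref": v.ref_aa,
                    "alt": v.alt_aa,
                    "domain": v.domain_label,
                    "n_carriers": v.n_carriers,
                    "carrier_ids": ",".join(map(str, v.carrier_ids)),
                }
                for v in self.unique_variants
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "n_sequences_scanned": self.n_sequences_scanned,
            "n_length_filtered": self.n_length_filtered,
            "n_unique_variants": self.n_unique,
            "n_carrier_sequences": self.n_carrier_sequences,
            "per_domain_counts": dict(self.per_domain_counts),
            "variants": self.to_dataframe().to_dict(orient="records"),
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def length_filter(
    panel: list[tuple[str, str]], required_length: int = 229
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str]]]:
    """Keep records of exactly the required length; list the rest with reasons.

    Records containing non-amino-acid characters are dropped with a warning.
    Returns ``(kept, dropped)`` where dropped entries are
    ``(id, length, reason)``.
    """
    kept, dropped = [], []
    for rec_id, seq in panel:
        bad = set(seq) - VALID_AA
        if bad:
            warnings.warn(
                f"record {rec_id}: non-amino-acid characters {sorted(bad)}; dropped",
                stacklevel=2,
            )
            dropped.append((rec_id, len(seq), "invalid characters"))
        elif len(seq) != required_length:
            dropped.append((rec_id, len(seq), "length"))
        else:
            kept.append((rec_id, seq))
    return kept, dropped


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


@dataclass
class SubstitutionScan:
    substitutions: list  # [(position, ref_aa, alt_aa), ...] reference coordinates
    indels: list  # [("ins"|"del", ref_position, length), ...]
    identity: float
    low_homology: bool


def call_substitutions(seq: str, reference: str) -> SubstitutionScan:
    """Call substitutions from a global pairwise alignment to the reference.

    Needleman–Wunsch with BLOSUM62 (gap open 10, extend 0.5).  Substitutions
    are called only at columns where both residues are aligned and differ;
    positions are 1-based reference coordinates.  Indels are reported
    separately.  Alignment identity < 50% attaches a low-homology warning.
    """
    if not seq or not reference:
        raise ValueError("empty sequence")
    aln = _make_aligner().align(reference, seq)[0]
    ref_blocks, seq_blocks = aln.aligned
    subs, indels = [], []
    matches = 0
    aligned_cols = 0
    prev_ref_end, prev_seq_end = 0, 0
    for (r0, r1), (s0, s1) in zip(ref_blocks, seq_blocks):
        if r0 > prev_ref_end:
            indels.append(("del", prev_ref_end + 1, r0 - prev_ref_end))
        if s0 > prev_seq_end:
            indels.append(("ins", prev_ref_end, s0 - prev_seq_end))
        for k in range(r1 - r0):
            a, b = reference[r0 + k], seq[s0 + k]
            aligned_cols += 1
            if a == b:
                matches += 1
            else:
                subs.append((r0 + k + 1, a, b))
        prev_ref_end, prev_seq_end = r1, s1
    if prev_ref_end < len(reference):
        indels.append(("del", prev_ref_end + 1, len(reference) - prev_ref_end))
    if prev_seq_end < len(seq):
        indels.append(("ins", prev_ref_end, len(seq) - prev_seq_end))
    identity = matches / aligned_cols if aligned_cols else 0.0
    low = identity < 0.5
    if low:
        warnings.warn(f"alignment identity {identity:.2f} < 0.50", stacklevel=2)
    return SubstitutionScan(subs, indels, identity, low)


def tabulate_panel(
    panel: list[tuple[str, str]],
    reference: str,
    domain_map: DomainMap = DEFAULT_DOMAIN_MAP,
    apply_length_filter: bool = True,
    required_length: int | None = None,
) -> VariantPanelReport:
    """Census of unique substitutions in a panel relative to the reference.

    Variants are keyed by (position, ref, alt) with carrier lists, classified
    by domain, and ordered by position then alternate residue — giving a
    report invariant to panel record order.
    """
    n_in = len(panel)
    if apply_length_filter:
        L = required_length if required_length is not None else len(reference)
        kept, dropped = length_filter(panel, L)
    else:
        kept, dropped = list(panel), []
    calls: dict[tuple[int, str, str], list] = {}
    indels = []
    low_ids = []
    carriers = set()
    for rec_id, seq in sorted(kept):
        scan = call_substitutions(seq, reference)
        if scan.low_homology:
            low_ids.append(rec_id)
        if scan.indels:
            indels.append((rec_id, scan.indels))
        if scan.substitutions:
            carriers.add(rec_id)
        for pos, ref_aa, alt_aa in scan.substitutions:
            calls.setdefault((pos, ref_aa, alt_aa), []).append(rec_id)
    unique = [
        VariantCall(pos, ref_aa, alt_aa, domain_map.classify(pos), sorted(ids))
        for (pos, ref_aa, alt_aa), ids in sorted(
            calls.items(), key=lambda kv: (kv[0][0], kv[0][2])
        )
    ]
    per_domain: dict[str, int] = {label: 0 for label, _, _ in domain_map.segments}
    for v in unique:
        per_domain[v.domain_label] += 1
    return VariantPanelReport(
        n_sequences_scanned=len(kept),
        n_length_filtered=n_in - len(kept),
        unique_variants=unique,
        per_domain_counts=per_domain,
        n_carrier_sequences=len(carriers),
        indels=indels,
        low_homology_ids=low_ids,
    )
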