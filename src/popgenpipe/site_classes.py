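"""Assignment of genomic positions to analysis site classes.

Classes: consistently 0-, 2- or 4-fold degenerate exonic positions,
conserved noncoding elements (three set variants), CNE neutral flank
references, and none. Positions carrying conflicting evidence are excluded
with an enumerable reason. All coordinates are 0-based half-open; VCF
positions are converted on entry (pos - 1).

Transcripts only contribute if complete: the assembled CDS starts with ATG,
ends in a stop codon, has length divisible by 3 and contains no internal
stop. A position receives a fold class only if every valid transcript
containing it agrees; 3-fold degenerate positions (e.g. Ile codon third
positions) are excluded rather than binned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Transcript",
    "SiteClassMap",
    "CNESet",
    "CLASS_CODES",
    "validate_transcript",
    "extract_cds",
    "degeneracy_by_codon",
    "classify_degeneracy",
    "build_cne_sets",
    "build_cne_flank_reference",
    "read_gff3_transcripts",
    "read_bed_intervals",
    "subtract_intervals",
    "merge_intervals",
]

# per-position class codes of the SiteClassMap array
CLASS_CODES = {
    "none": 0,
    "fold0": 1,
    "fold2": 2,
    "fold4": 3,
    "cne": 4,
    "cne_flank": 5,
    "excluded:inconsistent_degeneracy": 6,
    "excluded:invalid_transcript": 7,
    "excluded:threefold": 8,
    "excluded:phase": 9,
    "excluded:overlap": 10,
}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD_CODE = {}


def _genetic_code() -> dict[str, str]:
    global _STANDARD_CODE
    if not _STANDARD_CODE:
        from Bio.Data.CodonTable import standard_dna_table

        code = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            code[stop] = "*"
        _STANDARD_CODE = code
    return _STANDARD_CODE


@dataclass
class Transcript:
    """Ordered CDS intervals of one transcript (0-based half-open on the
    reference, listed in genomic order; minus-strand transcripts are
    reverse-complemented when the CDS is assembled)."""

    id: str
    strand: str
    cds: list[tuple[int, int]]
    valid: bool | None = None
    reason: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in transcript {self.id}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class CNESet:
    intervals: list[tuple[int, int]]
    variant: str = "noOverlap"

    def __post_init__(self):
        if self.variant not in ("noOverlap", "strict", "noOverlap_lt1kb"):
            raise ValueError(f"unknown CNE set variant {self.variant!r}")
        self.intervals = sorted(tuple(iv) for iv in self.intervals)

    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class SiteClassMap:
    """Per-position class code over a chromosome of given length."""

    codes: np.ndarray
    counts: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, length: int) -> "SiteClassMap":
        return cls(np.zeros(length, dtype=np.int8))

    def positions_of(self, class_name: str) -> np.ndarray:
        return np.nonzero(self.codes == CLASS_CODES[class_name])[0]

    def class_of(self, pos: int) -> str:
        return CODE_NAMES[int(self.codes[pos])]

    def summary(self) -> dict[str, int]:
        vals, cnt = np.unique(self.codes, return_counts=True)
        return {CODE_NAMES[int(v)]: int(c) for v, c in zip(vals, cnt)}


def validate_transcript(cds_sequence: str):
    """Completeness check on an assembled 5'->3' CDS.

    Valid iff length % 3 == 0, first codon ATG, last codon a stop, and no
    internal stop codon. Returns (valid, reason).
    """
    seq = cds_sequence.upper()
    if any(b not in "ACGT" for b in seq):
        return False, "ambiguous_base"
    if len(seq) % 3 != 0:
        return False, "length_not_multiple_of_3"
    if len(seq) < 6:
        return False, "too_short"
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != "ATG":
        return False, "no_start_codon"
    if codons[-1] not in ("TAA", "TAG", "TGA"):
        return False, "no_stop_codon"
    if any(c in ("TAA", "TAG", "TGA") for c in codons[:-1]):
        return False, "premature_stop"
    return True, ""


def extract_cds(transcript: Transcript, reference: str) -> str:
    """Assemble the transcript's CDS 5'->3' from the reference."""
    parts = [reference[s:e] for s, e in transcript.cds]
    seq = "".join(parts).upper()
    if transcript.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def degeneracy_by_codon() -> dict[str, tuple[int, int, int]]:
    """Synonymous-substitution count (0..3) per codon position for all 64
    codons, from exhaustive single-base substitution against the standard
    genetic code. Stop codons are treated as encoding '*'."""
    code = _genetic_code()
    table = {}
    for codon, aa in code.items():
        degs = []
        for p in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1:]
                if code[alt] == aa:
                    syn += 1
            degs.append(syn)
        table[codon] = tuple(degs)
    return table


_SYN_TO_CODE = {0: CLASS_CODES["fold0"], 1: CLASS_CODES["fold2"],
                2: CLASS_CODES["excluded:threefold"], 3: CLASS_CODES["fold4"]}


def classify_degeneracy(transcripts, reference: str,
                        site_map: SiteClassMap | None = None) -> SiteClassMap:
    """Assign fold classes to exonic reference positions.

    Per valid transcript, each CDS position's synonymous-substitution count
    maps to {fold0, fold2, fold4}; 3-fold positions are excluded. A
    position keeps a class only if every valid transcript containing it
    agrees; disagreement -> excluded:inconsistent_degeneracy. Positions
    covered only by invalid transcripts -> excluded:invalid_transcript.
    """
    if site_map is None:
        site_map = SiteClassMap.empty(len(reference))
    codes = site_map.codes
    deg_table = degeneracy_by_codon()
    assigned: dict[int, int] = {}
    conflict: set[int] = set()
    covered_invalid: set[int] = set()

    for tr in transcripts:
        cds_seq = extract_cds(tr, reference)
        tr.valid, tr.reason = validate_transcript(cds_seq)
        genome_pos = np.concatenate(
            [np.arange(s, e) for s, e in tr.cds]
        ) if tr.cds else np.empty(0, dtype=int)
        if not tr.valid:
            covered_invalid.update(int(p) for p in genome_pos)
            continue
        if tr.strand == "-":
            genome_pos = genome_pos[::-1]
        for i in range(0, len(cds_seq) - 2, 3):
            codon = cds_seq[i:i + 3]
            degs = deg_table[codon]
            for k in range(3):
                p = int(genome_pos[i + k])
                cls = _SYN_TO_CODE[degs[k]]
                prev = assigned.get(p)
                if prev is None:
                    assigned[p] = cls
                elif prev != cls:
                    conflict.add(p)

    for p, cls in assigned.items():
        codes[p] = cls
    for p in conflict:
        codes[p] = CLASS_CODES["excluded:inconsistent_degeneracy"]
    for p in covered_invalid:
        if p not in assigned and p not in conflict:
            codes[p] = CLASS_CODES["excluded:invalid_transcript"]
    return site_map


def merge_intervals(intervals):
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def subtract_intervals(intervals, to_remove):
    """Set difference of half-open interval lists (both need not be merged)."""
    removal = merge_intervals(to_remove)
    out = []
    for s, e in intervals:
        cur = s
        for rs, re_ in removal:
            if re_ <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, min(rs, e)))
            cur = max(cur, re_)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def build_cne_sets(raw_elements, exons, variant: str = "noOverlap") -> CNESet:
    """Derive a CNE analysis set from raw conserved elements and exons.

    noOverlap: trim away the exon-overlapping segments of each element
    (an element may split into several intervals). strict: drop any element
    with exon overlap entirely. noOverlap_lt1kb: the noOverlap treatment,
    additionally dropping elements whose original length is >= 1 kb.
    """
    exon_iv = merge_intervals(exons)
    elements = merge_intervals(raw_elements)
    out: list[tuple[int, int]] = []
    for s, e in elements:
        overlaps = any(s < xe and xs < e for xs, xe in exon_iv)
        if variant == "strict":
            if not overlaps:
                out.append((s, e))
            continue
        if variant == "noOverlap_lt1kb" and (e - s) >= 1000:
            continue
        if overlaps:
            out.extend(subtract_intervals([(s, e)], exon_iv))
        else:
            out.append((s, e))
    return CNESet(out, variant)


def build_cne_flank_reference(cnes: CNESet, exons, all_cnes: CNESet,
                              chrom_length: int | None = None):
    """Neutral flank reference intervals for each CNE.

    A CNE [s, e) of length L gets an upstream flank
    [s - 500 - ceil(L/2), s - 500) and a downstream flank
    [e + 500, e + 500 + floor(L/2)). Flanks are trimmed against exons and
    against every element of the full noOverlap CNE set, then clipped to
    the chromosome. A fully masked flank is simply absent.
    """
    masks = merge_intervals(list(exons) + list(all_cnes.intervals))
    flanks: list[tuple[int, int]] = []
    for s, e in cnes.intervals:
        L = e - s
        if L < 2:
            continue
        up_len = (L + 1) // 2
        down_len = L // 2
        cand = [(s - 500 - up_len, s - 500), (e + 500, e + 500 + down_len)]
        cand = [(max(0, a), b if chrom_length is None else min(b, chrom_length))
                for a, b in cand]
        cand = [(a, b) for a, b in cand if b > a]
        flanks.extend(subtract_intervals(cand, masks))
    return merge_intervals(flanks)


def assign_intervals(site_map: SiteClassMap, intervals, class_name: str,
                     overwrite: bool = False) -> SiteClassMap:
    """Stamp a class onto interval positions; by default only onto
    positions still classed 'none' (the partition is exclusive)."""
    code = CLASS_CODES[class_name]
    for s, e in intervals:
        seg = site_map.codes[s:e]
        if overwrite:
            seg[:] = code
        else:
            seg[seg == CLASS_CODES["none"]] = code
    return site_map


def read_gff3_transcripts(path) -> list[Transcript]:
    """Collect CDS features from a GFF3 file into transcripts keyed by
    their Parent (or ID when no Parent is given)."""
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ) if len(f) > 8 else {}
            tid = attrs.get("Parent", attrs.get("ID", f"{f[0]}:{f[3]}"))
            g = groups.setdefault(tid, {"strand": f[6], "cds": []})
            g["cds"].append((int(f[3]) - 1, int(f[4])))
    return [Transcript(tid, g["strand"], g["cds"]) for tid, g in groups.items()]


def read_bed_intervals(path) -> list[tuple[int, int]]:
    """BED3 intervals (0-based half-open), sorted."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            out.append((int(f[1]), int(f[2])))
    return sorted(out)


def write_class_bed(site_map: SiteClassMap, path, chrom: str = "chr1") -> None:
    """SiteClassMap as BED with a class column (runs of equal class)."""
    codes = site_map.codes
    with open(path, "w") as fh:
        if codes.size == 0:
            return
        change = np.nonzero(np.diff(codes))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [codes.size]])
        for s, e in zip(starts, ends):
            name = CODE_NAMES[int(codes[s])]
            if name != "none":
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
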