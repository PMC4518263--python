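"""miRNA-like eRNAs and their promoter target sites.

An eRNA is confirmed miRNA-like when it carries an exact copy of a miRNA
family's mature sequence or 7-nt seed (mature positions 2–8).  The family's
seed is then scanned against sense and antisense promoter sequences of the
enhancer's target genes for canonical sites (8mer, 7mer-m8, 7mer-A1 in
TargetScan nomenclature), and the mature sequence is scanned with a
position-weighted complementarity score.  Only (gene, family) pairs with
promoter sites but no 3'UTR site are retained, and significance per eRNA
comes from a shuffle bootstrap: permute the eRNA sequence, rerun the whole
identification, and count shuffles scoring at least the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, normalize_sequence, reverse_complement, subtract_intervals

__all__ = [
    "SeedFamily",
    "SiteMatch",
    "confirm_mir_region",
    "build_promoter",
    "build_utr3",
    "seed_site_scan",
    "alignment_site_scan",
    "promoter_unique_filter",
    "count_promoter_unique_matches",
    "shuffle_bootstrap",
    "shuffle_sequence",
]


@dataclass(frozen=True)
class SeedFamily:
    """A miRNA family: 7-nt seed (mature positions 2–8) plus mature sequences."""

    family_id: str
    seed7: str
    mature_seqs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seed = normalize_sequence(self.seed7)
        if len(seed) != 7:
            raise ValueError("seed7 must be exactly 7 nt")
        object.__setattr__(self, "seed7", seed)
        object.__setattr__(
            self, "mature_seqs", tuple(normalize_sequence(m) for m in self.mature_seqs)
        )


@dataclass(frozen=True)
class SiteMatch:
    """One candidate target site in a promoter or 3'UTR sequence."""

    gene_id: str
    family_id: str
    region_kind: str  # promoter | utr3
    strand_scanned: str  # sense | antisense
    position: int  # offset of the site's first base in region coordinates
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | alignment
    score: float | None = None


def confirm_mir_region(
    erna_seq: str, family: SeedFamily
) -> tuple[int, str] | None:
    """Leftmost exact occurrence of a mature sequence or the seed in the eRNA.

    Both orientations are searched (a reverse-strand hit is reported with
    orientation ``antisense``); returns ``(position, orientation)`` or
    ``None``.  U and T are interchangeable.
    """
    seq = normalize_sequence(erna_seq)
    patterns = list(family.mature_seqs) + [family.seed7]
    best: tuple[int, str] | None = None
    for pat in patterns:
        for orientation, probe in (("sense", pat), ("antisense", reverse_complement(pat))):
            pos = seq.find(probe)
            if pos != -1 and (
                best is None
                or pos < best[0]
                or (pos == best[0] and orientation == "sense" and best[1] == "antisense")
            ):
                best = (pos, orientation)
    return best


def build_promoter(
    gene: GeneModel, all_genes: Sequence[GeneModel]
) -> list[GenomicInterval]:
    """Promoter intervals: 1000 bp upstream to 200 bp downstream of the TSS
    (strand-aware), minus every other gene's transcript span.  May be empty."""
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - 1000, tss + 200
    else:
        lo, hi = tss - 200, tss + 1000
    lo = max(0, lo)
    if hi <= lo:
        return []
    window = GenomicInterval(gene.chrom, lo, hi, gene.strand)
    cutters = [
        g.interval for g in all_genes
        if g.gene_id != gene.gene_id and g.chrom == gene.chrom
    ]
    return subtract_intervals(window, cutters)


def build_utr3(gene: GeneModel) -> GenomicInterval | None:
    """3'UTR: from the end of the coding region to the transcript end.

    ``None`` for noncoding genes or a zero-length UTR.
    """
    if gene.coding_end is None:
        return None
    iv = gene.interval
    if gene.strand == "+":
        start, end = gene.coding_end, iv.end
    else:
        start, end = iv.start, gene.coding_end
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, gene.strand)


def _classify_seed_sites(seq: str, family: SeedFamily) -> list[tuple[int, str]]:
    """All canonical seed sites in a sense sequence as (position, type).

    rc7 = reverse complement of the 7-nt seed.  8mer: rc7 followed by A;
    7mer-m8: rc7 not followed by A; 7mer-A1: reverse complement of seed
    positions 2–7 followed by A, excluding offsets that are the tail of an
    8mer (already reported one base to the left).
    """
    rc7 = reverse_complement(family.seed7)
    rc6a = rc7[1:] + "A"
    sites: list[tuple[int, str]] = []
    pos = seq.find(rc7)
    while pos != -1:
        nxt = seq[pos + 7: pos + 8]
        sites.append((pos, "8mer" if nxt == "A" else "7mer-m8"))
        pos = seq.find(rc7, pos + 1)
    pos = seq.find(rc6a)
    while pos != -1:
        if pos == 0 or seq[pos - 1] != rc7[0]:
            sites.append((pos, "7mer-A1"))
        pos = seq.find(rc6a, pos + 1)
    return sorted(sites)


def _site_length(site_type: str) -> int:
    return 8 if site_type == "8mer" else 7


def seed_site_scan(
    region_seq: str,
    family: SeedFamily,
    scan_antisense: bool = True,
    gene_id: str = "",
    region_kind: str = "promoter",
) -> list[SiteMatch]:
    """Canonical seed sites on the sense (and optionally antisense) strand.

    Antisense positions are mapped back to sense coordinates of the site's
    first base; duplicate (position, family, type) records are collapsed.
    """
    seq = normalize_sequence(region_seq)
    out: dict[tuple[int, str, str], SiteMatch] = {}
    for pos, site_type in _classify_seed_sites(seq, family):
        key = (pos, site_type, "sense")
        out[key] = SiteMatch(gene_id, family.family_id, region_kind, "sense", pos, site_type)
    if scan_antisense:
        rc = reverse_complement(seq)
        n = len(seq)
        for pos, site_type in _classify_seed_sites(rc, family):
            sense_pos = n - pos - _site_length(site_type)
            key = (sense_pos, site_type, "antisense")
            # a palindromic site found on both strands counts once
            if (sense_pos, site_type, "sense") in out:
                continue
            out[key] = SiteMatch(
                gene_id, family.family_id, region_kind, "antisense", sense_pos, site_type
            )
    return sorted(out.values(), key=lambda s: (s.position, s.site_type, s.strand_scanned))


# complementarity scores: Watson-Crick +5, G:U wobble +1, mismatch -3;
# miRNA positions 2-8 are weighted x2
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}
MATCH_SCORE = 5.0
WOBBLE_SCORE = 1.0
MISMATCH_SCORE = -3.0
SEED_WEIGHT = 2.0


def _pair_score(mir_base: str, target_base: str) -> float:
    """Score of one miRNA base opposite one target base (both 5'->3' DNA).

    Pairing is antiparallel, so the miRNA base pairs the complement of what
    appears in the target string read 5'->3'; equivalently the pair is a
    match when miRNA base == complement(target base) — i.e. (mir, target)
    in the Watson-Crick set directly.
    """
    if (mir_base, target_base) in _WC:
        return MATCH_SCORE
    if (mir_base, target_base) in _WOBBLE:
        return WOBBLE_SCORE
    return MISMATCH_SCORE


def alignment_site_scan(
    region_seq: str,
    mature: str,
    threshold: float = 80.0,
    scan_antisense: bool = True,
    gene_id: str = "",
    family_id: str = "",
    region_kind: str = "promoter",
) -> list[SiteMatch]:
    """Ungapped complementarity scan of a mature miRNA along a sequence.

    The mature sequence (3'->5') is slid along each target window (5'->3');
    per-position scores are +5 for Watson-Crick, +1 for G:U wobble, -3 for
    a mismatch, doubled at miRNA positions 2-8.  Windows with total score
    >= ``threshold`` are reported; both strands are scanned.
    """
    mature = normalize_sequence(mature)
    if len(mature) < 15:
        raise ValueError("mature sequence must be >= 15 nt")
    seq = normalize_sequence(region_seq)
    m = len(mature)
    weights = np.ones(m)
    weights[1:8] = SEED_WEIGHT  # miRNA positions 2-8
    # reversed mature aligns left-to-right along the target window; weight
    # vector follows the same reversal
    rev = mature[::-1]
    rev_weights = weights[::-1]
    lut = np.full((5, 5), MISMATCH_SCORE)
    code = {b: i for i, b in enumerate("ACGTN")}
    for (a, b), s in [(p, MATCH_SCORE) for p in _WC] + [(p, WOBBLE_SCORE) for p in _WOBBLE]:
        lut[code[a], code[b]] = s
    lut[code["N"], :] = MISMATCH_SCORE
    lut[:, code["N"]] = MISMATCH_SCORE

    def _scan(target: str, strand: str, n_sense: int) -> list[SiteMatch]:
        if len(target) < m:
            return []
        t = np.frombuffer(target.encode(), dtype=np.uint8)
        tcode = np.zeros(t.size, dtype=np.intp)
        for b, i in code.items():
            tcode[t == ord(b)] = i
        rcode = np.array([code[b] for b in rev], dtype=np.intp)
        n_win = len(target) - m + 1
        idx = np.arange(n_win)[None, :] + np.arange(m)[:, None]
        scores = (lut[rcode[:, None], tcode[idx]] * rev_weights[:, None]).sum(axis=0)
        hits = []
        for i in np.flatnonzero(scores >= threshold):
            pos = int(i) if strand == "sense" else n_sense - int(i) - m
            hits.append(
                SiteMatch(
                    gene_id, family_id, region_kind, strand, pos, "alignment",
                    float(scores[i]),
                )
            )
        return hits

    out = _scan(seq, "sense", len(seq))
    if scan_antisense:
        out += _scan(reverse_complement(seq), "antisense", len(seq))
    return sorted(out, key=lambda s: (s.position, s.strand_scanned))


def promoter_unique_filter(
    promoter_sites: Sequence[SiteMatch], utr3_sites: Sequence[SiteMatch]
) -> bool:
    """Retain a (eRNA, gene, family) triple iff the promoter has at least
    one site and the 3'UTR has none."""
    return len(promoter_sites) > 0 and len(utr3_sites) == 0


def count_promoter_unique_matches(
    erna_seq: str,
    families: Sequence[SeedFamily],
    promoter_seqs: Mapping[str, str],
    utr3_seqs: Mapping[str, str],
    mode: str = "seed",
    threshold: float = 80.0,
) -> int:
    """The bootstrap statistic: number of retained (gene, family) pairs.

    A family contributes only if the eRNA is confirmed to carry its mature
    sequence or seed; each of the eRNA's target genes is then scanned and
    retained under the promoter-unique rule.
    """
    count = 0
    for family in families:
        if confirm_mir_region(erna_seq, family) is None:
            continue
        for gene_id, prom_seq in promoter_seqs.items():
            if mode == "seed":
                prom = seed_site_scan(prom_seq, family, gene_id=gene_id)
                utr = (
                    seed_site_scan(utr3_seqs[gene_id], family, gene_id=gene_id,
                                   region_kind="utr3")
                    if gene_id in utr3_seqs and len(utr3_seqs[gene_id]) >= 8
                    else []
                )
            elif mode == "alignment":
                prom, utr = [], []
                for mat in family.mature_seqs:
                    prom += alignment_site_scan(
                        prom_seq, mat, threshold, gene_id=gene_id,
                        family_id=family.family_id,
                    )
                    if gene_id in utr3_seqs and len(utr3_seqs[gene_id]) >= len(mat):
                        utr += alignment_site_scan(
                            utr3_seqs[gene_id], mat, threshold, gene_id=gene_id,
                            family_id=family.family_id, region_kind="utr3",
                        )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if promoter_unique_filter(prom, utr):
                count += 1
    return count


def shuffle_sequence(
    seq: str, rng: np.random.Generator, dinucleotide: bool = False
) -> str:
    """Random permutation of a sequence's characters.

    With ``dinucleotide`` an Altschul–Erickson-style shuffle preserves the
    dinucleotide composition (random Eulerian walk on the transition
    multigraph).
    """
    seq = normalize_sequence(seq)
    if not dinucleotide:
        chars = np.array(list(seq))
        return "".join(chars[rng.permutation(len(chars))])
    if len(seq) < 3:
        return seq
    # Altschul-Erickson: shuffle each vertex's outgoing edge list, keeping
    # one edge per vertex reserved to reach the terminal character last.
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(200):
        trial = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        out = [seq[0]]
        cur = seq[0]
        ok = True
        counts = {a: 0 for a in trial}
        for _step in range(len(seq) - 1):
            lst = trial.get(cur)
            if lst is None or counts[cur] >= len(lst):
                ok = False
                break
            nxt = lst[counts[cur]]
            counts[cur] += 1
            out.append(nxt)
            cur = nxt
        if ok and len(out) == len(seq):
            return "".join(out)
    # fall back to plain permutation if no Eulerian walk completed
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(len(chars))])


def shuffle_bootstrap(
    erna_seq: str,
    scan_closure: Callable[[str], float],
    B: int = 100,
    rng_seed: int = 0,
    dinucleotide: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Shuffle-bootstrap p-value for one eRNA.

    ``scan_closure`` maps a sequence to the identification statistic (here:
    retained promoter-unique match count).  ``p = (1 + #{shuffled >=
    observed}) / (1 + B)`` — the add-one estimator never returns 0.
    Returns ``(p, observed, shuffled_statistics)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng_seed)
    observed = float(scan_closure(normalize_sequence(erna_seq)))
    shuffled = np.array(
        [
            float(scan_closure(shuffle_sequence(erna_seq, rng, dinucleotide)))
            for _ in range(B)
        ]
    )
    p = (1 + int((shuffled >= observed).sum())) / (1 + B)
    return float(p), observed, shuffled
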