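"""Synthetic multi-tissue worlds with planted, recoverable structure.

The generator emulates the pipeline's real inputs — enhancer–target maps
per tissue, strand-aware RNA-seq contigs, per-region BPKM expression,
promoter/3'UTR/eRNA sequences, a miRNA seed-family table and ncRNA
family-hit tables — with every effect planted and recorded in a truth
record: which enhancers transcribe, the latent eRNA–target correlation
``rho``, the state-dependent target-gene shift ``delta`` (z-score scale),
planted promoter seed sites, and one ncRNA family with excess eRNA hits.

Geometry guarantees exact recovery of planted states: genes sit on a
regular grid with wide intergenic gaps, one enhancer template per gap, far
enough apart that calling windows never capture a neighbouring template's
contig, and planted contigs are clipped to intergenic space so the
gene-overlap filter never removes them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import ERNA, NO_ERNA, ErnaCall, RnaContig
from .core import Enhancer, GeneIndex, GeneModel, GenomicInterval
from .correlation import BpkmTable, background_regions, flanking_regions, matched_gene_region
from .mirtargets import SeedFamily, reverse_complement

__all__ = ["SimConfig", "SyntheticWorld", "generate_world", "plant_seed_sites",
           "simulate_group_means", "random_sequence"]

ALPHABET = np.array(list("ACGT"))
_ALPHABET_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: geometric constants of the planted world (bp)
GENE_LEN_RANGE = (2000, 3000)
ENH_LEN_RANGE = (500, 1500)
JITTER = 400
FLANK_SPACE = 3000  # gene-free room reserved beyond the calling window
MIN_SLOT = 18000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic world.

    Defaults reflect the study conditions: 12 tissues, ~200 intergenic
    enhancers per tissue with a ±3 kb calling window, a moderate planted
    eRNA–target correlation and a half-standard-deviation expression shift
    for genes targeted by transcribing enhancers.
    """

    n_tissues: int = 12
    chrom_length: int = 4_000_000
    n_genes: int = 200
    n_enhancers: int = 200
    erna_fraction: float = 0.4
    rho: float = 0.6
    delta: float = 0.5
    seed_site_rate: float = 0.3
    family_enrichment: float = 0.15
    rng_seed: int = 0
    other_enrichment: float = 0.05
    # secondary knobs (documented in the methods note)
    shared_fraction: float = 0.6
    multi_target_rate: float = 0.1
    sigma: float = 0.5
    log_bpkm_mean: float = 0.0
    gene_bpkm_mean: float = 10.0
    gene_bpkm_sd: float = 1.0
    n_families: int = 8
    n_mirna_families: int = 3
    n_other_enriched: int = 4
    n_mirlike: int = 10
    erna_seq_length: int = 80
    promoter_seq_length: int = 1200
    utr3_seq_length: int = 400
    background_hit_rate: float = 0.03
    decoy_rate: float = 0.5
    window: int = 3000
    margin: int = 3000
    total_mapped_bases: float = 1e9

    def __post_init__(self) -> None:
        if not (0 <= self.erna_fraction <= 1):
            raise ValueError("erna_fraction must be in [0, 1]")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must be in (-1, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_enhancers > self.n_genes:
            raise ValueError("n_enhancers must be <= n_genes (one template per gap)")
        if self.n_tissues < 1 or self.n_genes < 2 or self.n_enhancers < 1:
            raise ValueError("need >= 1 tissue, >= 2 genes, >= 1 enhancer")
        slot = self.chrom_length // self.n_genes
        if slot < MIN_SLOT:
            raise ValueError(
                f"infeasible packing: slot {slot} bp < {MIN_SLOT} bp; "
                "increase chrom_length or decrease n_genes"
            )


@dataclass
class SyntheticWorld:
    """One generated world plus its ground-truth record."""

    config: SimConfig
    chrom: str
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    enhancers_by_tissue: dict[str, list[Enhancer]]
    contigs_by_tissue: dict[str, list[RnaContig]]
    bpkm: BpkmTable
    gene_bpkm: pd.DataFrame
    seed_families: list[SeedFamily]
    family_classes: dict[str, str]
    erna_seqs: dict[str, str]
    promoter_seqs: dict[str, str]
    utr3_seqs: dict[str, str]
    hits_real: pd.DataFrame
    hits_control: pd.DataFrame
    n_real_queries: int
    n_control_queries: int
    truth: dict

    @property
    def tissues(self) -> list[str]:
        return sorted(self.enhancers_by_tissue)

    @property
    def enhancer_index(self) -> dict[tuple[str, str], Enhancer]:
        return {
            (t, e.enhancer_id): e
            for t, enhs in self.enhancers_by_tissue.items()
            for e in enhs
        }

    def planted_calls(self) -> list[ErnaCall]:
        """The planted transcription states as ErnaCall records."""
        calls = []
        for tissue in self.tissues:
            for enh in self.enhancers_by_tissue[tissue]:
                contig = self.truth["contigs"].get((tissue, enh.enhancer_id))
                if contig is None:
                    calls.append(ErnaCall(enh.enhancer_id, tissue, NO_ERNA))
                else:
                    calls.append(
                        ErnaCall(enh.enhancer_id, tissue, ERNA, contig, (contig,))
                    )
        return calls

    def write(self, outdir: str | Path) -> None:
        """Emit the world as the plain-text formats the readers consume."""
        from . import io  # local import to avoid a cycle

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_gene_models(out / "genes.tsv", self.genes)
        io.write_enhancers(
            out / "enhancers.tsv",
            [e for t in self.tissues for e in self.enhancers_by_tissue[t]],
        )
        for tissue in self.tissues:
            io.write_contigs(out / f"contigs.{tissue}.bed", self.contigs_by_tissue[tissue])
        io.write_bpkm_table(out / "bpkm.tsv", self.bpkm)
        self.gene_bpkm.to_csv(out / "gene_bpkm.tsv", sep="\t", index=False)
        io.write_fasta(out / "ernas.fasta", self.erna_seqs)
        io.write_fasta(out / "promoters.fasta", self.promoter_seqs)
        io.write_fasta(out / "utr3.fasta", self.utr3_seqs)
        io.write_seed_families(out / "families.tsv", self.seed_families, self.family_classes)
        self.hits_real.to_csv(out / "hits_real.tsv", sep="\t", index=False)
        self.hits_control.to_csv(out / "hits_control.tsv", sep="\t", index=False)
        with open(out / "chrom_sizes.tsv", "w") as fh:
            for chrom, size in sorted(self.chrom_sizes.items()):
                fh.write(f"{chrom}\t{size}\n")
        truth = _jsonable(self.truth)
        truth["config"] = asdict(self.config)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True, default=str)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, k))): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, RnaContig):
        return {
            "chrom": obj.interval.chrom,
            "start": obj.interval.start,
            "end": obj.interval.end,
            "strand": obj.interval.strand,
            "bpkm": obj.bpkm,
        }
    return obj


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET_BYTES[rng.integers(0, 4, size=length)].tobytes().decode()


def plant_seed_sites(
    promoter_seqs: Mapping[str, str],
    seed_families: Sequence[SeedFamily],
    rate: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[dict]]:
    """Overwrite exact canonical seed sites into promoter sequences.

    Each promoter independently receives one planted site with probability
    ``rate``: a uniformly chosen family and site type (8mer / 7mer-m8 /
    7mer-A1) at a uniform position.  Returns the edited sequences and the
    complete truth list of planted sites.
    """
    site_types = ("8mer", "7mer-m8", "7mer-A1")
    out: dict[str, str] = {}
    truth: list[dict] = []
    for gene_id in sorted(promoter_seqs):
        seq = promoter_seqs[gene_id]
        if len(seq) < 9 or rng.random() >= rate or not seed_families:
            out[gene_id] = seq
            continue
        family = seed_families[int(rng.integers(0, len(seed_families)))]
        site_type = site_types[int(rng.integers(0, 3))]
        rc7 = reverse_complement(family.seed7)
        if site_type == "8mer":
            site = rc7 + "A"
        elif site_type == "7mer-m8":
            site = rc7 + "G"  # trailing non-A blocks accidental 8mer promotion
        else:
            blocker = "C" if rc7[0] != "C" else "G"  # must differ from rc7[0]
            site = blocker + rc7[1:] + "A"
        pos = int(rng.integers(0, len(seq) - len(site) + 1))
        seq = seq[:pos] + site + seq[pos + len(site):]
        record_pos = pos if site_type != "7mer-A1" else pos + 1
        out[gene_id] = seq
        truth.append(
            {
                "gene_id": gene_id,
                "family_id": family.family_id,
                "position": record_pos,
                "site_type": site_type,
            }
        )
    return out, truth


def _strip_sites(seq: str, families: Sequence[SeedFamily], rng: np.random.Generator) -> str:
    """Rewrite a sequence until it contains no canonical site of any family
    on either strand (used for 3'UTRs that must stay site-free)."""
    from .mirtargets import seed_site_scan

    for _ in range(50):
        if all(not seed_site_scan(seq, fam) for fam in families):
            return seq
        seq = random_sequence(rng, len(seq))
    raise RuntimeError("could not generate a site-free sequence")


def generate_world(config: SimConfig) -> SyntheticWorld:
    """Generate one deterministic synthetic world (see module docstring)."""
    rng = np.random.default_rng(config.rng_seed)
    chrom = "chrS"
    chrom_sizes = {chrom: config.chrom_length}
    tissues = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    slot = config.chrom_length // config.n_genes
    w = config.window

    # --- genes on a regular grid, >= 7 kb gaps ------------------------------
    gene_lens = rng.integers(GENE_LEN_RANGE[0], GENE_LEN_RANGE[1] + 1, config.n_genes)
    gene_strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        start = i * slot + 500
        end = start + int(gene_lens[i])
        iv = GenomicInterval(chrom, start, end, str(gene_strands[i]))
        utr_len = int(rng.integers(200, min(800, iv.length // 2)))
        coding_end = end - utr_len if gene_strands[i] == "+" else start + utr_len
        genes.append(GeneModel(f"gene{i:04d}", iv, coding_end))
    gene_by_id = {g.gene_id: g for g in genes}
    gene_index = GeneIndex(genes)

    # --- enhancer templates: one per gap, windows mutually disjoint ---------
    templ_len = rng.integers(ENH_LEN_RANGE[0], ENH_LEN_RANGE[1] + 1, config.n_enhancers)
    shared = rng.random(config.n_enhancers) < config.shared_fraction
    owner = rng.integers(0, config.n_tissues, config.n_enhancers)
    second_target = rng.random(config.n_enhancers) < config.multi_target_rate
    templates = []
    for i in range(config.n_enhancers):
        gene_end = genes[i].interval.end
        next_start = genes[i + 1].interval.start if i + 1 < config.n_genes else config.chrom_length
        lo = gene_end + config.margin + FLANK_SPACE + JITTER
        hi = next_start - config.margin - FLANK_SPACE - JITTER - int(templ_len[i])
        if hi <= lo:
            raise ValueError("infeasible packing: no room for enhancer template")
        start = int(rng.integers(lo, hi + 1))
        targets = {genes[i].gene_id}
        if second_target[i] and i + 1 < config.n_genes:
            targets.add(genes[i + 1].gene_id)
        templates.append(
            {
                "template_id": f"enh{i:04d}",
                "start": start,
                "length": int(templ_len[i]),
                "targets": frozenset(targets),
                "shared": bool(shared[i]),
                "owner": tissues[int(owner[i])],
                "gap": (gene_end, next_start),
            }
        )

    # --- per-tissue instances, states and planted contigs -------------------
    enhancers_by_tissue: dict[str, list[Enhancer]] = {t: [] for t in tissues}
    contigs_by_tissue: dict[str, list[RnaContig]] = {t: [] for t in tissues}
    states: dict[tuple[str, str], str] = {}
    planted_contigs: dict[tuple[str, str], RnaContig] = {}
    for tpl in templates:
        present = tissues if tpl["shared"] else [tpl["owner"]]
        for tissue in present:
            jitter = int(rng.integers(-JITTER, JITTER + 1))
            start = tpl["start"] + jitter
            iv = GenomicInterval(chrom, start, start + tpl["length"])
            enh = Enhancer(tpl["template_id"], iv, tissue, tpl["targets"])
            enhancers_by_tissue[tissue].append(enh)
            transcribing = rng.random() < config.erna_fraction
            states[(tissue, tpl["template_id"])] = ERNA if transcribing else NO_ERNA
            gap_lo, gap_hi = tpl["gap"]
            if transcribing:
                s5 = int(rng.integers(iv.start - w, iv.end + w))
                strand = "+" if rng.random() < 0.5 else "-"
                drawn = int(np.clip(rng.lognormal(np.log(500), 0.6), 50, 3000))
                # clip the contig body to the gene-free gap so the planted
                # eRNA always survives the gene-overlap filter
                plus_avail = gap_hi - s5
                minus_avail = s5 + 1 - gap_lo
                if strand == "+" and plus_avail < 50 <= minus_avail:
                    strand = "-"
                elif strand == "-" and minus_avail < 50 <= plus_avail:
                    strand = "+"
                if strand == "+":
                    length = max(1, min(drawn, plus_avail))
                    civ = GenomicInterval(chrom, s5, s5 + length, "+")
                else:
                    length = max(1, min(drawn, minus_avail))
                    civ = GenomicInterval(chrom, s5 - length + 1, s5 + 1, "-")
                contig = RnaContig(civ, bpkm=0.0)  # bpkm filled after expression draw
                planted_contigs[(tissue, tpl["template_id"])] = contig
            elif rng.random() < config.decoy_rate:
                # decoy contig whose 5' start must stay out of every window;
                # place it inside the gene body (exercises the overlap filter)
                g = genes[int(rng.integers(0, config.n_genes))]
                s5 = int(rng.integers(g.interval.start, g.interval.end))
                civ = GenomicInterval(chrom, s5, s5 + 120, "+")
                contigs_by_tissue[tissue].append(RnaContig(civ, bpkm=float(rng.lognormal(0, 0.5))))

    # --- expression: correlated eRNA/target pairs, independent backgrounds --
    mu_e = config.log_bpkm_mean
    sigma = config.sigma
    bpkm_rows: list[tuple[str, str, float]] = []
    seen_regions: set[tuple[str, str]] = set()

    def emit(region_id: str, tissue: str, value: float) -> None:
        if (region_id, tissue) not in seen_regions:
            seen_regions.add((region_id, tissue))
            bpkm_rows.append((region_id, tissue, float(value)))

    pair_records = []
    enh_index = {
        (t, e.enhancer_id): e for t, es in enhancers_by_tissue.items() for e in es
    }
    for tpl in templates:
        for tissue in (tissues if tpl["shared"] else [tpl["owner"]]):
            key = (tissue, tpl["template_id"])
            if states[key] != ERNA:
                continue
            contig = planted_contigs[key]
            u = rng.normal()
            erna_bpkm = float(np.exp(mu_e + sigma * u))
            contig = RnaContig(contig.interval, bpkm=erna_bpkm)
            planted_contigs[key] = contig
            contigs_by_tissue[tissue].append(contig)
            emit(contig.interval.region_id, tissue, erna_bpkm)
            for gid in sorted(tpl["targets"]):
                v = config.rho * u + np.sqrt(1 - config.rho**2) * rng.normal()
                region = matched_gene_region(gene_by_id[gid], contig.interval.length)
                emit(region.region_id, tissue, float(np.exp(mu_e + sigma * v)))
                pair_records.append(
                    {"tissue": tissue, "enhancer_id": tpl["template_id"],
                     "gene_id": gid, "u": u, "v": float(v)}
                )
            enh = enh_index[key]
            for _label, _side, iv in flanking_regions(enh, contig, gene_index, window=w):
                emit(iv.region_id, tissue, float(rng.lognormal(mu_e, sigma)))

    # background regions exactly as the correlation profile will sample them
    calls = []
    for tissue in tissues:
        for enh in enhancers_by_tissue[tissue]:
            key = (tissue, enh.enhancer_id)
            if states[key] == ERNA:
                for gid in sorted(enh.target_gene_ids):
                    calls.append(
                        (
                            ErnaCall(enh.enhancer_id, tissue, ERNA,
                                     planted_contigs[key], (planted_contigs[key],)),
                            enh,
                            gene_by_id[gid],
                        )
                    )
    bg = background_regions(calls, genes, chrom_sizes, rng_seed=config.rng_seed,
                            margin=config.margin)
    for row in bg.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        emit(iv.region_id, row.tissue, float(rng.lognormal(mu_e, sigma)))

    # --- gene-level expression with the state-dependent shift ---------------
    shifted: dict[tuple[str, str], bool] = {}
    for tissue in tissues:
        for enh in enhancers_by_tissue[tissue]:
            if states[(tissue, enh.enhancer_id)] == ERNA:
                for gid in enh.target_gene_ids:
                    shifted[(gid, tissue)] = True
    gene_rows = []
    for gene in genes:
        for tissue in tissues:
            base = rng.normal(config.gene_bpkm_mean, config.gene_bpkm_sd)
            if shifted.get((gene.gene_id, tissue)):
                base += config.delta * config.gene_bpkm_sd
            gene_rows.append(
                {"gene_id": gene.gene_id, "tissue": tissue,
                 "bpkm": float(max(base, 0.01))}
            )
    gene_bpkm = pd.DataFrame(gene_rows)
    for row in gene_rows:
        emit(row["gene_id"], row["tissue"], row["bpkm"])

    table = BpkmTable(
        pd.DataFrame(bpkm_rows, columns=["region_id", "tissue", "bpkm"]),
        {t: config.total_mapped_bases for t in tissues},
    )

    # --- seed families and sequences ----------------------------------------
    seed_families: list[SeedFamily] = []
    seen_seeds: set[str] = set()
    while len(seed_families) < config.n_families:
        seed = random_sequence(rng, 7)
        if seed in seen_seeds:
            continue
        seen_seeds.add(seed)
        fid = f"fam{len(seed_families):03d}"
        mature = random_sequence(rng, 1) + seed + random_sequence(rng, 14)
        seed_families.append(SeedFamily(fid, seed, (mature,)))
    family_classes = {
        f.family_id: ("miRNA" if i < config.n_mirna_families else "other")
        for i, f in enumerate(seed_families)
    }
    mir_families = seed_families[: config.n_mirna_families]

    promoter_raw = {
        g.gene_id: random_sequence(rng, config.promoter_seq_length) for g in genes
    }
    promoter_seqs, planted_sites = plant_seed_sites(
        promoter_raw, seed_families, config.seed_site_rate, rng
    )
    utr3_seqs = {
        g.gene_id: random_sequence(rng, config.utr3_seq_length) for g in genes
    }

    # --- miRNA-like eRNAs: carry a mature copy; target promoter gets a site,
    # target 3'UTR is kept site-free so the promoter-unique rule retains it --
    erna_seqs: dict[str, str] = {}
    mirlike_truth = []
    n_mirlike = min(config.n_mirlike, config.n_enhancers)
    for j in range(n_mirlike):
        tpl = templates[j]
        family = mir_families[j % len(mir_families)] if mir_families else seed_families[0]
        seq = random_sequence(rng, config.erna_seq_length)
        mature = family.mature_seqs[0]
        pos = int(rng.integers(0, len(seq) - len(mature) + 1))
        seq = seq[:pos] + mature + seq[pos + len(mature):]
        erna_seqs[tpl["template_id"]] = seq
        primary = min(tpl["targets"])
        rc7 = reverse_complement(family.seed7)
        site = rc7 + "A"
        prom = promoter_seqs[primary]
        spos = int(rng.integers(0, len(prom) - len(site) + 1))
        promoter_seqs[primary] = prom[:spos] + site + prom[spos + len(site):]
        utr3_seqs[primary] = _strip_sites(utr3_seqs[primary], [family], rng)
        mirlike_truth.append(
            {"enhancer_id": tpl["template_id"], "family_id": family.family_id,
             "gene_id": primary, "mature_pos": pos, "promoter_site_pos": spos}
        )

    # --- family-hit tables with one enriched miRNA family -------------------
    real_queries = sorted(
        f"erna|{t}|{e}" for (t, e), s in states.items() if s == ERNA
    )
    n_real = len(real_queries)
    n_control = n_real
    control_queries = [f"ctrl|{i:05d}" for i in range(n_control)]
    enriched: dict[str, float] = {}
    for fam in mir_families:
        enriched[fam.family_id] = config.family_enrichment
    n_other = min(config.n_other_enriched,
                  max(0, config.n_families - config.n_mirna_families))
    for fam in seed_families[config.n_mirna_families: config.n_mirna_families + n_other]:
        enriched[fam.family_id] = config.other_enrichment
    planted_family = mir_families[0].family_id if mir_families else seed_families[0].family_id
    hit_rows_real, hit_rows_ctrl = [], []
    for fam in seed_families:
        p_real = config.background_hit_rate + enriched.get(fam.family_id, 0.0)
        p_ctrl = config.background_hit_rate
        for q in real_queries:
            if rng.random() < p_real:
                hit_rows_real.append(
                    (q, fam.family_id, family_classes[fam.family_id],
                     float(np.round(rng.uniform(20, 80), 2)))
                )
        for q in control_queries:
            if rng.random() < p_ctrl:
                hit_rows_ctrl.append(
                    (q, fam.family_id, family_classes[fam.family_id],
                     float(np.round(rng.uniform(20, 80), 2)))
                )
    cols = ["query_id", "family_id", "family_class", "score"]
    hits_real = pd.DataFrame(hit_rows_real, columns=cols)
    hits_control = pd.DataFrame(hit_rows_ctrl, columns=cols)

    # --- truth record --------------------------------------------------------
    pairs = pd.DataFrame(pair_records)
    realized_r = float("nan")
    if len(pairs) >= 3:
        e_vals = np.exp(mu_e + sigma * pairs["u"].to_numpy())
        g_vals = np.exp(mu_e + sigma * pairs["v"].to_numpy())
        realized_r = float(np.corrcoef(e_vals, g_vals)[0, 1])
    truth = {
        "states": dict(states),
        "contigs": planted_contigs,
        "latent_rho": config.rho,
        "realized_bpkm_r": realized_r,
        "n_pairs": len(pairs),
        "planted_delta": config.delta,
        "shifted": sorted("|".join(k) for k in shifted),
        "planted_sites": planted_sites,
        "mirlike": mirlike_truth,
        "planted_family": planted_family,
        "enriched_families": dict(enriched),
        "templates": [
            {k: (sorted(v) if isinstance(v, frozenset) else v)
             for k, v in tpl.items() if k != "gap"}
            for tpl in templates
        ],
    }

    return SyntheticWorld(
        config=config,
        chrom=chrom,
        chrom_sizes=chrom_sizes,
        genes=genes,
        enhancers_by_tissue=enhancers_by_tissue,
        contigs_by_tissue={t: sorted(v, key=lambda c: (c.interval.start, c.interval.end))
                           for t, v in contigs_by_tissue.items()},
        bpkm=table,
        gene_bpkm=gene_bpkm,
        seed_families=seed_families,
        family_classes=family_classes,
        erna_seqs=erna_seqs,
        promoter_seqs=promoter_seqs,
        utr3_seqs=utr3_seqs,
        hits_real=hits_real,
        hits_control=hits_control,
        n_real_queries=n_real,
        n_control_queries=n_control,
        truth=truth,
    )


def simulate_group_means(
    n_groups: int,
    delta: float,
    rng_seed: int,
    max_members_per_state: int = 4,
    sd: float = 1.0,
) -> list[tuple[float, float]]:
    """Group-level simulator for t-test calibration studies.

    Each group averages 1..``max_members_per_state`` per-tissue z-scores
    per state; transcribing members are shifted by ``delta``.  Returns
    ``(mean_z_eRNA, mean_z_no_eRNA)`` pairs.
    """
    rng = np.random.default_rng(rng_seed)
    pairs = []
    for _ in range(n_groups):
        m1 = int(rng.integers(1, max_members_per_state + 1))
        m2 = int(rng.integers(1, max_members_per_state + 1))
        pairs.append(
            (
                float(rng.normal(delta, sd, m1).mean()),
                float(rng.normal(0.0, sd, m2).mean()),
            )
        )
    return pairs
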