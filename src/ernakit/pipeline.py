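"""End-to-end pipeline over one synthetic world.

Runs every stage in order — state calling, correlation profile,
cross-tissue grouped comparison, family enrichment, miRNA-like target-site
discovery with the shuffle bootstrap — and collects plain tabular results.
Fixed seeds make the whole run byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from .calling import ERNA, ErnaCall, call_states, state_proportions
from .correlation import correlation_profile
from .crosstissue import (
    TestResult,
    build_groups,
    compare_state_expression,
    group_paired_means,
    paired_t_test,
    zscore_by_tissue,
)
from .enrichment import family_enrichment, mirna_vs_other, sample_matched_controls
from .mirtargets import count_promoter_unique_matches, shuffle_bootstrap
from .simulate import SimConfig, SyntheticWorld, generate_world

__all__ = ["PipelineResult", "run_pipeline", "write_results"]


@dataclass
class PipelineResult:
    world: SyntheticWorld
    calls: list[ErnaCall]
    proportions: pd.DataFrame
    correlations: pd.DataFrame
    groups: pd.DataFrame
    paired_means: pd.DataFrame
    paired_t: TestResult | None
    rank_sum: pd.DataFrame
    enrichment: pd.DataFrame
    class_comparison: TestResult | None
    class_points: pd.DataFrame
    mirlike: pd.DataFrame
    controls: list

    def tables(self) -> dict[str, pd.DataFrame]:
        named = {
            "proportions": self.proportions.reset_index(),
            "correlations": self.correlations,
            "groups": self.groups,
            "paired_means": self.paired_means,
            "rank_sum": self.rank_sum,
            "enrichment": self.enrichment,
            "class_points": self.class_points,
            "mirlike": self.mirlike,
        }
        return named


def _bootstrap_seed(base: int, index: int) -> int:
    return int((base * 100_003 + 7919 * (index + 1)) % (2**31))


def run_pipeline(
    config: SimConfig | None = None,
    world: SyntheticWorld | None = None,
    bootstrap_B: int = 100,
) -> PipelineResult:
    """Generate (or accept) a world and run every analysis stage on it."""
    if world is None:
        world = generate_world(config or SimConfig())
    config = world.config
    genes = world.genes

    # 1) state calling per tissue
    calls: list[ErnaCall] = []
    for tissue in world.tissues:
        calls.extend(
            call_states(
                world.enhancers_by_tissue[tissue],
                world.contigs_by_tissue[tissue],
                genes,
                window=config.window,
                margin=config.margin,
            )
        )
    proportions = state_proportions(calls)

    # 2) eRNA-target correlation profile with backgrounds
    enh_index = world.enhancer_index
    corr = correlation_profile(
        calls, enh_index, genes, world.bpkm, world.chrom_sizes,
        rng_seed=config.rng_seed, window=config.window,
    )
    correlations = pd.DataFrame(
        [{"tissue": c.tissue, "label": c.label, "n": c.n, "r": c.r, "p": c.p} for c in corr]
    )

    # 3) cross-tissue grouped comparison
    z = zscore_by_tissue(world.gene_bpkm)
    zmap = {(g, t): v for g, t, v in zip(z["gene_id"], z["tissue"], z["z"])}
    groups = build_groups(
        [e for t in world.tissues for e in world.enhancers_by_tissue[t]],
        calls,
        rng_seed=config.rng_seed,
    )
    group_rows, pair_rows = [], []
    for i, grp in enumerate(groups):
        mean_e, mean_n = group_paired_means(grp, zmap)
        group_rows.append(
            {
                "group_index": i,
                "gene_id": grp.gene_id,
                "chrom": grp.anchor.chrom,
                "anchor_start": grp.anchor.start,
                "anchor_end": grp.anchor.end,
                "n_members": len(grp.members),
                "members": ";".join(f"{t}:{e}:{s}" for t, e, s in grp.members),
            }
        )
        pair_rows.append(
            {"group_index": i, "gene_id": grp.gene_id,
             "mean_z_eRNA": mean_e, "mean_z_no_eRNA": mean_n}
        )
    groups_df = pd.DataFrame(group_rows)
    paired_means = pd.DataFrame(pair_rows)
    paired_t = None
    if len(paired_means) >= 2:
        try:
            paired_t = paired_t_test(
                list(zip(paired_means["mean_z_eRNA"], paired_means["mean_z_no_eRNA"]))
            )
        except ValueError:
            paired_t = None
    ranks = compare_state_expression(calls, enh_index, world.gene_bpkm)
    rank_sum = pd.DataFrame(
        [
            {"tissue": t, "statistic": r.statistic, "p": r.p, "n": r.n}
            for t, r in sorted(ranks.items())
        ]
    )

    # 4) ncRNA family enrichment against matched controls
    ernas = [c.contig for c in calls if c.state == ERNA]
    controls = sample_matched_controls(
        ernas, genes, world.chrom_sizes, rng_seed=config.rng_seed, margin=config.margin
    )
    enr = family_enrichment(
        world.hits_real, world.hits_control,
        world.n_real_queries, world.n_control_queries,
    )
    enrichment_df = pd.DataFrame(
        [
            {
                "family_id": r.family_id, "family_class": r.family_class,
                "k1": r.k1, "n1": r.n1, "k2": r.k2, "n2": r.n2,
                "z": r.z, "p": r.p, "significant": r.significant,
            }
            for r in enr
        ]
    )
    class_test, class_points, _lines = mirna_vs_other(enr)

    # 5) miRNA-like target sites + shuffle bootstrap
    mirlike_rows = []
    for idx, (enh_id, seq) in enumerate(sorted(world.erna_seqs.items())):
        target_ids = sorted(
            set().union(
                *(
                    enh_index[(t, enh_id)].target_gene_ids
                    for t in world.tissues
                    if (t, enh_id) in enh_index
                )
            )
        )
        proms = {g: world.promoter_seqs[g] for g in target_ids if g in world.promoter_seqs}
        utrs = {g: world.utr3_seqs[g] for g in target_ids if g in world.utr3_seqs}

        def closure(s: str) -> int:
            return count_promoter_unique_matches(
                s, world.seed_families, proms, utrs, mode="seed"
            )

        p, observed, _ = shuffle_bootstrap(
            seq, closure, B=bootstrap_B,
            rng_seed=_bootstrap_seed(config.rng_seed, idx),
        )
        mirlike_rows.append(
            {"enhancer_id": enh_id, "observed_matches": int(observed), "bootstrap_p": p}
        )
    mirlike = pd.DataFrame(mirlike_rows)

    return PipelineResult(
        world=world,
        calls=calls,
        proportions=proportions,
        correlations=correlations,
        groups=groups_df,
        paired_means=paired_means,
        paired_t=paired_t,
        rank_sum=rank_sum,
        enrichment=enrichment_df,
        class_comparison=class_test,
        class_points=class_points,
        mirlike=mirlike,
        controls=controls,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage's table (and the call list) as TSV under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    call_rows = []
    for c in result.calls:
        iv = c.contig.interval if c.contig else None
        call_rows.append(
            {
                "enhancer_id": c.enhancer_id,
                "tissue": c.tissue,
                "state": c.state,
                "contig_chrom": iv.chrom if iv else "NA",
                "contig_start": iv.start if iv else "NA",
                "contig_end": iv.end if iv else "NA",
                "contig_strand": iv.strand if iv else "NA",
                "contig_bpkm": c.contig.bpkm if c.contig else "NA",
            }
        )
    pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    for name, df in result.tables().items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    io.write_bed(out / "controls.bed", result.controls)
    summary = []
    if result.paired_t is not None:
        summary.append(
            {"test": "paired_t", "statistic": result.paired_t.statistic,
             "p": result.paired_t.p, "n": result.paired_t.n}
        )
    if result.class_comparison is not None:
        summary.append(
            {"test": "mirna_vs_other", "statistic": result.class_comparison.statistic,
             "p": result.class_comparison.p, "n": result.class_comparison.n}
        )
    pd.DataFrame(summary).to_csv(out / "tests.tsv", sep="\t", index=False)
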