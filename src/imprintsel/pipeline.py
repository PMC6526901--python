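"""End-to-end orchestration: gates -> recombination screen -> model fits ->
LRT decisions -> per-site consensus -> gap masking -> fixation check -> MK
battery -> enrichment, with deterministic reports.

The input directory follows the bundle layout written by
:func:`imprintsel.simulate.make_study_bundle`; every stage decision is
recorded per gene so summary counts are re-derivable from the per-gene
table.  Partial failures are isolated per gene and never abort the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import persite, recomb
from .codon_model import (
    FitOptions,
    fit_model,
    lineage_specific_call,
    lrt,
    preferred_site_posteriors,
)
from .core_io import (
    OrthologCluster,
    cluster_size_gate,
    column_gap_fraction,
    quality_gate,
    read_codon_fasta,
    read_gene_sets,
    read_hit_table,
    read_newick,
)
from .fixation import site_conservation, snp_matrix_from_haplotypes
from .genesets import (
    GeneRecord,
    age_distribution_test,
    assign_age_class,
    ps_enrichment,
    summarize_categories,
)
from .mk import aggregate_battery, count_mk


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    alpha: float = 0.05
    quality_threshold: float = 0.6
    gap_cutoff: float = 0.40
    min_species: int = 6
    posterior_threshold: float = 0.95
    consensus_min_methods: int = 2
    seed: int = 0
    starts: int = 2
    freqs_mode: str = "f3x4"
    run_recomb: bool = True
    run_persite: bool = True
    recomb_permutations: int = 50
    emit_fdr: bool = True


def _bh_fdr(pvals: list[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis over a bundle directory; returns the summary."""
    inp = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    genesets = read_gene_sets(inp / "genesets.tsv")
    labels = dict(zip(genesets["gene_id"], genesets["set_label"]))
    gene_ids = sorted(labels)
    hits = read_hit_table(inp / "hits.tsv") if (inp / "hits.tsv").exists() else None

    per_gene_rows: list[dict] = []
    site_rows: list[dict] = []
    records: list[GeneRecord] = []
    mk_counts = []
    fit_options = FitOptions(starts=config.starts, freqs_mode=config.freqs_mode)

    for gene in gene_ids:
        row = {"gene": gene, "set_label": labels[gene], "status": "ok",
               "excluded_stage": "", "reason": ""}
        try:
            result = _process_gene(gene, inp, config, fit_options, note, site_rows)
            row.update(result)
        except Exception as exc:  # isolate per-gene failures
            row["status"] = "error"
            row["reason"] = str(exc)
            note(f"{gene}\tERROR\t{exc}")
        per_gene_rows.append(row)
        if row.get("status") == "ok" and not row.get("excluded_stage"):
            records.append(
                GeneRecord(
                    gene, labels[gene],
                    omega=row.get("pairwise_omega"),
                    ps_lineage=bool(row.get("ps_lineage")),
                    ps_site=bool(row.get("ps_site")),
                    age_class=row.get("age_class"),
                )
            )
        if row.get("mk") is not None:
            mk_counts.append(row.pop("mk"))
        else:
            row.pop("mk", None)

    # age classes
    if hits is not None:
        for rec in records:
            sub = hits[hits["gene_id"] == rec.gene_id]
            if len(sub):
                rec.age_class = assign_age_class(sub)
    for row in per_gene_rows:
        rec = next((r for r in records if r.gene_id == row["gene"]), None)
        row["age_class"] = rec.age_class if rec is not None else ""

    # optional multiple-testing transparency column
    if config.emit_fdr:
        tested = [r for r in per_gene_rows if r.get("p_m8_vs_m7") not in (None, "")]
        if tested:
            fdr = _bh_fdr([r["p_m8_vs_m7"] for r in tested])
            for r, q in zip(tested, fdr):
                r["q_m8_vs_m7"] = q

    per_gene = pd.DataFrame(per_gene_rows)
    per_gene.to_csv(out / "per_gene.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(site_rows).to_csv(out / "sites.tsv", sep="\t", index=False,
                                   float_format="%.6g")

    summary = summarize_categories(records, set_labels=("iMEG", "iPEG"))
    summary.to_csv(out / "summary_categories.tsv", sep="\t", float_format="%.6g")

    battery = aggregate_battery(mk_counts) if mk_counts else None
    if battery is not None:
        pd.DataFrame(battery.per_gene).to_csv(
            out / "mk_per_gene.tsv", sep="\t", index=False, float_format="%.6g"
        )
        agg = {k: getattr(battery, k) for k in
               ("DN", "DS", "PN", "PS", "dnds", "pnps", "FI", "eFI", "alpha",
                "DoS", "NI_TG")}
        pd.DataFrame([agg]).to_csv(out / "mk_battery.tsv", sep="\t", index=False,
                                   float_format="%.6g")

    enrichment = _enrichment_tables(records, inp, config, note)
    if enrichment is not None:
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")

    age_p = None
    a = [r.age_class for r in records if r.set_label == "iMEG" and r.age_class is not None]
    b = [r.age_class for r in records if r.set_label == "iPEG" and r.age_class is not None]
    if a and b:
        age_p = age_distribution_test(a, b, seed=config.seed)
        note(f"age_distribution\tiMEG_vs_iPEG\tp={age_p:.6g}")

    (out / "run_config.json").write_text(
        json.dumps(asdict(config), sort_keys=True, indent=1) + "\n"
    )
    (out / "log.txt").write_text("\n".join(log) + "\n")
    report = {
        "n_genes": len(gene_ids),
        "n_processed": len(records),
        "n_ps": sum(r.ps_any for r in records),
        "age_test_p": age_p,
        "battery": None if battery is None else {
            "FI": battery.FI, "eFI": battery.eFI, "alpha": battery.alpha,
            "DoS": battery.DoS, "NI_TG": battery.NI_TG,
        },
    }
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=float) + "\n"
    )
    return report


def _process_gene(gene, inp, config, fit_options, note, site_rows) -> dict:
    row: dict = {"mk": None}
    gene_dir = inp / "genes" / gene
    alignment = read_codon_fasta(gene_dir / "alignment.fasta")
    tree = read_newick(gene_dir / "tree.nwk")
    cluster = OrthologCluster(gene, alignment, tree)

    gate = cluster_size_gate(cluster, config.min_species)
    note(f"{gene}\tcluster_size_gate\t{'pass' if gate.passed else 'fail'}\t{gate.reason}")
    if not gate.passed:
        return {**row, "excluded_stage": "cluster_gate", "reason": gate.reason}

    qual = quality_gate(alignment, config.quality_threshold, drop_and_retry=True)
    note(f"{gene}\tquality_gate\t{'pass' if qual.passed else 'fail'}\t{qual.reason}")
    row["quality_score"] = qual.score
    if not qual.passed:
        return {**row, "excluded_stage": "quality_gate", "reason": qual.reason}
    alignment = qual.alignment

    if config.run_recomb and alignment.n_taxa >= 4:
        calls = recomb.maxchi_scan(
            alignment, permutations=config.recomb_permutations, seed=config.seed
        )
        calls += recomb.bootscan_like_scan(
            alignment,
            window=min(200, alignment.n_codons * 3 // 2),
            replicates=config.recomb_permutations,
            seed=config.seed,
        )
        removed = recomb.recombination_consensus(calls)
        removed = [t for t in removed if t != gene]
        if removed:
            note(f"{gene}\trecombination\tremoved\t{','.join(removed)}")
            alignment = alignment.subset_taxa(
                [t for t in alignment.taxa if t not in removed]
            )
        row["recomb_removed"] = ",".join(removed)

    if not any(n.foreground for n in tree.postorder()):
        tree.set_foreground([gene])
    cluster = OrthologCluster(gene, alignment, tree)

    # model fits: M0 anchors branch lengths and kappa
    m0 = fit_model(cluster, "M0", fit_options)
    base_opts = FitOptions(
        starts=fit_options.starts, freqs_mode=fit_options.freqs_mode, base_fit=m0
    )
    m1 = fit_model(cluster, "M1Neutral", base_opts)
    ma = fit_model(cluster, "ModelA", base_opts)
    ma0 = fit_model(cluster, "ModelAnull", base_opts)
    m7 = fit_model(cluster, "M7", base_opts)
    m8 = fit_model(cluster, "M8", base_opts)
    m8a = fit_model(cluster, "M8a", base_opts)

    lineage = lineage_specific_call(ma, ma0, m1, alpha=config.alpha)
    t_m7 = lrt(m8, m7)
    t_m8a = lrt(m8, m8a)
    site_lrt_sig = config.alpha >= 1.0 or (
        t_m7.p_value < config.alpha and t_m8a.p_value < config.alpha
    )
    row.update(
        m0_omega=m0.params.site_classes[0].omega,
        m0_kappa=m0.params.kappa,
        lnL_m0=m0.lnL, lnL_m7=m7.lnL, lnL_m8=m8.lnL, lnL_m8a=m8a.lnL,
        lnL_ma=ma.lnL, lnL_ma_null=ma0.lnL, lnL_m1=m1.lnL,
        p_ma_vs_null=lineage.lrt_vs_null.p_value,
        p_ma_vs_m1=lineage.lrt_vs_m1.p_value,
        p_m8_vs_m7=t_m7.p_value, p_m8_vs_m8a=t_m8a.p_value,
        ps_lineage=lineage.positive, near_threshold=lineage.near_threshold,
    )

    confirmed_masked: list[int] = []
    if config.run_persite:
        eb = preferred_site_posteriors(m8, threshold=config.posterior_threshold)
        calls = persite.eb_site_calls(eb)
        recon = persite.reconstruct_ancestors(cluster, m0)
        calls += persite.slac_all_sites(recon, threshold=config.alpha)
        calls += persite.fel_all_sites(cluster, m0, threshold=config.alpha)
        confirmed = persite.consensus_ps_sites(calls, config.consensus_min_methods)
        gaps = column_gap_fraction(alignment)
        confirmed_masked = persite.mask_sites_by_gap(confirmed, gaps, config.gap_cutoff)
        for call in calls:
            if call.passed:
                site_rows.append(
                    {"gene": gene, "site": call.site, "method": call.method,
                     "direction": call.direction, "score": call.score,
                     "confirmed": call.site in confirmed_masked,
                     "gap_fraction": gaps[call.site - 1]}
                )
        note(f"{gene}\tconsensus_sites\t{len(confirmed)}\tmasked->{len(confirmed_masked)}")
        row["n_confirmed_sites"] = len(confirmed_masked)
        row["ps_site"] = bool(site_lrt_sig and confirmed_masked)
    else:
        row["n_confirmed_sites"] = 0
        row["ps_site"] = bool(site_lrt_sig)

    # pairwise omega of the focal sequence against the closest relative
    focal_seq = alignment.sequences[alignment.taxa.index(gene)]
    other = next(t for t in alignment.taxa if t != gene)
    from .codon_model import estimate_pairwise_omega

    pw = estimate_pairwise_omega(focal_seq, alignment.sequences[alignment.taxa.index(other)])
    row["pairwise_omega"] = pw.omega

    # population data: MK counts and fixation check
    pop_path = inp / "populations" / f"{gene}.fasta"
    out_path = inp / "populations" / f"{gene}_outgroup.fasta"
    if pop_path.exists() and out_path.exists():
        pop = read_codon_fasta(pop_path)
        outgroup = read_codon_fasta(out_path).sequences[0]
        row["mk"] = count_mk(pop.sequences, outgroup, gene=gene)
        if confirmed_masked:
            snps = snp_matrix_from_haplotypes(gene, pop.sequences[0], pop.sequences,
                                              pop.taxa)
            reports = site_conservation(snps, pop.sequences[0], confirmed_masked)
            row["n_fixed_sites"] = sum(r.fixed for r in reports)
            for r in reports:
                note(f"{gene}\tfixation\tsite={r.site}\tfraction={r.fraction_reference:.4f}")
    return row


def _enrichment_tables(records, inp, config, note):
    controls_path = inp / "controls.tsv"
    if not controls_path.exists() or not records:
        return None
    controls = pd.read_csv(controls_path, sep="\t")
    rows = []
    for target_label in ("iPEG", "iMEG"):
        target = [r for r in records if r.set_label == target_label]
        if not target:
            continue
        for control_label, sub in controls.groupby("set_label"):
            for kind in ("lineage", "site"):
                tflags = [getattr(r, f"ps_{kind}") for r in target]
                cflags = sub[f"ps_{kind}"].astype(bool).tolist()
                try:
                    res = ps_enrichment(tflags, cflags)
                except Exception as exc:
                    note(f"enrichment\t{target_label}\t{control_label}\t{kind}\tskipped: {exc}")
                    continue
                rows.append(
                    {"target": target_label, "control": control_label, "kind": kind,
                     "odds_ratio": res.odds_ratio, "p_value": res.p_value,
                     "corrected": res.corrected,
                     "table": str(res.table)}
                )
                note(
                    f"enrichment\t{target_label}\t{control_label}\t{kind}"
                    f"\tOR={res.odds_ratio:.3g}\tp={res.p_value:.3g}"
                )
    return pd.DataFrame(rows) if rows else None
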