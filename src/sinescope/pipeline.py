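"""End-to-end orchestration with one config, one seed, and a manifest.

Every stage draws its randomness from a named substream of the global
seed, so stages can be rerun independently yet reproducibly and two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

import sinescope
from sinescope import aligndist, calibration, methylation, seqstats, splicing, synthetic
from sinescope.io_formats import (
    GenomeSequence,
    write_bed,
    write_fasta,
    write_gtf,
    write_methylation_table,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "stats", "distances", "splice", "methylation")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "genome_length": 200_000,
        "gc_fraction": 0.41,
        "n_elements": 30,
        "sub_rate": 0.02,
        "tandem_prob": 0.0,
        "nested_prob": 0.0,
        "spliced_prob": 0.15,
        "tsd_len_range": [8, 20],
        "tail_len_range": [10, 50],
        "n_genes": 10,
        "exon_in_element_prob": 0.4,
        "n_individuals": 8,
        "tissues": ["muscle", "testis"],
        "depth_range": [10, 60],
        "background_mean": 0.85,
        "dm_fraction": 0.4,
        "delta": 0.4,
        "overdispersion": 0.05,
        "indiv_sd": 0.2,
        "coupling_beta": 3.0,
        "expression_noise_sd": 0.1,
    },
    "thresholds": {
        "min_depth": 10,
        "max_depth": 300,
        "max_missing": 0.5,
        "p_threshold": 0.01,
        "min_abs_diff": 0.3,
        "min_cpg": 10,
        "reps": 10_000,
        "alpha": 0.01,
        "clock_alpha": 4.6e-9,
        "scan_min_identity": 0.7,
        "scan_min_len": 100,
        "distances_max_seqs": 30,
    },
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the stage name."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2**63)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(user: dict | None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, user or {})
    bad = set(cfg["stages"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_elements_tsv(elements, categories, path: Path) -> None:
    cat_by_id = {c.element_id: c for c in categories}
    with open(path, "w") as fh:
        fh.write(
            "element_id\tchrom\tstart\tend\tstrand\ttsd_seq\ttsd_len\theadbody_len\t"
            "tail_len\tclass\tmethod\ttandem_group\tnested_parent\tcategory\tnearest_gene\n"
        )
        for el in elements:
            cat = cat_by_id.get(el.element_id)
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        el.element_id,
                        el.full_span.chrom,
                        el.full_span.start,
                        el.full_span.end,
                        el.strand,
                        el.tsd.sequence if el.tsd else ".",
                        el.tsd.length if el.tsd else 0,
                        el.headbody_length,
                        el.tail_length,
                        el.class_label,
                        el.boundary_method,
                        el.tandem_group if el.tandem_group is not None else ".",
                        el.nested_parent or ".",
                        cat.category if cat else ".",
                        (cat.nearest_gene if cat and cat.nearest_gene else "."),
                    ]
                )
                + "\n"
            )


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Run the configured stages in dependency order under ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    for key, value in th.items():
        logger.info("threshold %s = %s", key, value)
    stages = cfg["stages"]
    artifacts: dict[str, Path] = {}
    state: dict = {}

    spec = synthetic.ConsensusSpec()
    consensus = synthetic.build_consensus(spec, seed=stage_seed(seed, "consensus"))
    donor, acceptor = splicing.find_dual_sites(spec)[0]

    if "simulate" in stages:
        sim = cfg["simulate"]
        bg = synthetic.generate_background(
            sim["genome_length"], sim["gc_fraction"], seed=stage_seed(seed, "background")
        )
        genome, truth = synthetic.implant_elements(
            bg,
            consensus,
            sim["n_elements"],
            tsd_len_range=tuple(sim["tsd_len_range"]),
            tail_len_range=tuple(sim["tail_len_range"]),
            sub_rate=sim["sub_rate"],
            tandem_prob=sim["tandem_prob"],
            nested_prob=sim["nested_prob"],
            spliced_prob=sim["spliced_prob"],
            splice_sites=(donor, acceptor),
            seed=stage_seed(seed, "implant"),
        )
        genes = synthetic.synthesize_annotation(
            genome,
            truth,
            sim["n_genes"],
            exon_in_element_prob=sim["exon_in_element_prob"],
            seed=stage_seed(seed, "annotation"),
            consensus_spec=spec,
        )
        meth = synthetic.simulate_methylomes(
            genome,
            truth,
            genes=genes,
            n_individuals=sim["n_individuals"],
            tissues=tuple(sim["tissues"]),
            depth_range=tuple(sim["depth_range"]),
            background_mean=sim["background_mean"],
            dm_fraction=sim["dm_fraction"],
            delta=sim["delta"],
            overdispersion=sim["overdispersion"],
            indiv_sd=sim["indiv_sd"],
            seed=stage_seed(seed, "methylomes"),
        )
        cats = calibration.position_annotation([t.span for t in truth], genes)
        e2g = {
            truth[i].element_id: c.nearest_gene
            for i, c in enumerate(cats)
            if c.category == "proximal" and c.nearest_gene
        }
        rng = np.random.default_rng(stage_seed(seed, "coupling"))
        coupling = {}
        for eid in sorted(meth.dm_truth):
            if eid in e2g:
                coupling[eid] = "+" if rng.random() < 0.5 else "-"
        expr = synthetic.simulate_expression(
            genes,
            meth,
            coupling,
            beta=sim["coupling_beta"],
            noise_sd=sim["expression_noise_sd"],
            seed=stage_seed(seed, "expression"),
            element_to_gene=e2g,
        )
        write_fasta([genome], out / "genome.fa")
        write_fasta([GenomeSequence("consensus", consensus)], out / "consensus.fa")
        write_gtf(genes, out / "genes.gtf")
        meth_dir = out / "meth"
        meth_dir.mkdir(exist_ok=True)
        for sid, recs in meth.records.items():
            write_methylation_table(recs, meth_dir / f"{sid}.tsv")
        with open(out / "design.tsv", "w") as fh:
            fh.write("sample_id\tindividual\ttissue\n")
            for sid, ind, tis in meth.design:
                fh.write(f"{sid}\t{ind}\t{tis}\n")
        expr.to_csv(out / "expression.tsv", sep="\t")
        truth_json = {
            "elements": [
                {
                    "element_id": t.element_id,
                    "span": [t.span.chrom, t.span.start, t.span.end, t.strand],
                    "tsd": t.tsd_seq,
                    "class": t.class_label,
                    "spliced": t.spliced,
                    "tandem_group": t.tandem_group,
                    "nested_parent": t.nested_parent,
                }
                for t in truth
            ],
            "dm_elements": meth.dm_truth,
            "coupling": coupling,
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
        for name in (
            "genome.fa",
            "consensus.fa",
            "genes.gtf",
            "design.tsv",
            "expression.tsv",
            "truth.json",
        ):
            artifacts[name] = out / name
        state.update(genome=genome, truth=truth, genes=genes, meth=meth, expr=expr)

    if "calibrate" in stages:
        genome = state.get("genome")
        if genome is None:
            raise RuntimeError("calibrate stage requires the simulate stage output")
        hits = calibration.scan_hits(
            genome,
            consensus,
            min_identity=th["scan_min_identity"],
            min_len=th["scan_min_len"],
        )
        elements, rejected = calibration.calibrate_all(genome, hits)
        elements = calibration.detect_structures(elements, genome=genome)
        cats = calibration.position_annotation(elements, state.get("genes", []))
        _write_elements_tsv(elements, cats, out / "elements.tsv")
        write_bed(
            [el.full_span for el in elements],
            out / "elements.bed",
            names=[el.element_id for el in elements],
        )
        artifacts["elements.tsv"] = out / "elements.tsv"
        artifacts["elements.bed"] = out / "elements.bed"
        state.update(elements=elements, categories=cats)
        logger.info("calibrated %d elements (%d rejected)", len(elements), len(rejected))

    if "stats" in stages:
        elements = state.get("elements")
        genome = state.get("genome")
        if elements is None or genome is None:
            raise RuntimeError("stats stage requires the calibrate stage output")
        with open(out / "stats.tsv", "w") as fh:
            fh.write(
                "element_id\tregion\tlength\tgc\tn_cpg\toe\tcpg_island\tdivergence\tt_mya\n"
            )
            for el in elements:
                regions = {"full": el.full_span, "headbody": el.headbody_span}
                if el.tail_span:
                    regions["tail"] = el.tail_span
                if el.tsd:
                    regions["tsd"] = el.tsd.left_span
                for name, iv in regions.items():
                    s = genome.sequence[iv.start : iv.end]
                    try:
                        stats = seqstats.composition(s)
                    except ValueError:
                        continue
                    if name == "headbody":
                        d = seqstats.p_distance(s, consensus)
                        est = seqstats.divergence_time(d, th["clock_alpha"])
                        div, tmya = f"{d:.4f}", f"{est.t_mya:.2f}"
                    else:
                        div, tmya = ".", "."
                    fh.write(
                        f"{el.element_id}\t{name}\t{stats.length}\t{stats.gc:.4f}\t"
                        f"{stats.n_cpg}\t{stats.oe:.4f}\t"
                        f"{int(seqstats.is_cpg_island(stats))}\t{div}\t{tmya}\n"
                    )
        artifacts["stats.tsv"] = out / "stats.tsv"

    if "distances" in stages:
        elements = state.get("elements")
        genome = state.get("genome")
        if elements is None or genome is None:
            raise RuntimeError("distances stage requires the calibrate stage output")
        cap = int(th["distances_max_seqs"])
        chosen = elements[:cap]
        seqs = {}
        for el in chosen:
            s = genome.sequence[el.headbody_span.start : el.headbody_span.end]
            if el.strand == "-":
                from sinescope.io_formats import revcomp

                s = revcomp(s)
            seqs[el.element_id] = s
        if len(seqs) >= 3:
            dm = aligndist.distance_matrix(seqs)
            emb = aligndist.pca_embed(dm, k=2)
            with open(out / "dm.tsv", "w") as fh:
                fh.write("id\t" + "\t".join(dm.ids) + "\n")
                for i, row in enumerate(dm.matrix):
                    fh.write(dm.ids[i] + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
            with open(out / "pca.tsv", "w") as fh:
                fh.write(
                    "# explained_variance: "
                    + " ".join(f"{v:.4f}" for v in emb.explained_variance)
                    + "\n"
                )
                fh.write("id\tPC1\tPC2\n")
                for i, eid in enumerate(dm.ids):
                    fh.write(
                        f"{eid}\t{emb.coordinates[i, 0]:.4f}\t{emb.coordinates[i, 1]:.4f}\n"
                    )
            artifacts["dm.tsv"] = out / "dm.tsv"
            artifacts["pca.tsv"] = out / "pca.tsv"

    if "splice" in stages:
        elements = state.get("elements")
        genes = state.get("genes")
        genome = state.get("genome")
        if elements is None or genes is None:
            raise RuntimeError("splice stage requires calibrate and simulate outputs")
        selected = splicing.select_cds_partial_overlaps(elements, genes)
        signals = []
        for el in selected:
            raw = splicing.mark_splice_signals(el, genes, genome)
            s = genome.sequence[el.headbody_span.start : el.headbody_span.end]
            if el.strand == "-":
                from sinescope.io_formats import revcomp

                s = revcomp(s)
            for sig in raw:
                proj = splicing.project_to_consensus(sig, s, consensus)
                if proj is not None:
                    signals.append(proj)
        window = (spec.head_len + 1, spec.head_len + 2 * spec.repeat_len + 1)
        profile = splicing.signal_profile(signals, window)
        thr = splicing.null_threshold(
            n_positions=window[1] - window[0] + 1,
            n_signals=max(profile.n_signals, 1),
            reps=th["reps"],
            alpha=th["alpha"],
            seed=stage_seed(seed, "null"),
        )
        hot = splicing.hot_sites(profile, thr)
        with open(out / "signals.tsv", "w") as fh:
            fh.write("element_id\telement_offset\tconsensus_pos\tkind\ttranscript_id\n")
            for s in signals:
                fh.write(
                    f"{s.element_id}\t{s.element_offset}\t{s.consensus_pos}\t{s.kind}\t{s.transcript_id}\n"
                )
        with open(out / "profile.tsv", "w") as fh:
            fh.write("consensus_pos\tcount\n")
            for pos in sorted(profile.counts):
                fh.write(f"{pos}\t{profile.counts[pos]}\n")
        with open(out / "hotsites.tsv", "w") as fh:
            fh.write(f"# k={thr.k} tail_prob={thr.tail_prob_at_k:.5f}\n")
            for pos in hot:
                fh.write(f"{pos}\n")
        for name in ("signals.tsv", "profile.tsv", "hotsites.tsv"):
            artifacts[name] = out / name
        state["signals"] = signals

    if "methylation" in stages:
        elements = state.get("elements")
        meth = state.get("meth")
        if elements is None or meth is None:
            raise RuntimeError("methylation stage requires calibrate and simulate outputs")
        records = [r for recs in meth.records.values() for r in recs]
        filtered = methylation.filter_cpgs(
            records,
            min_depth=th["min_depth"],
            max_depth=th["max_depth"],
            max_missing=th["max_missing"],
        )
        spans = {el.element_id: el.full_span for el in elements}
        em = methylation.element_methylation(filtered, spans)
        tissues = tuple(cfg["simulate"]["tissues"])
        results = methylation.differential_elements(
            em,
            meth.design,
            tissues=tissues,
            min_cpg=th["min_cpg"],
            p_threshold=th["p_threshold"],
            min_abs_diff=th["min_abs_diff"],
        )
        with open(out / "dm_elements.tsv", "w") as fh:
            fh.write("element_id\tn_cpg\tW\tp_value\teffect\tdm\n")
            for r in results:
                fh.write(
                    f"{r.element_id}\t{r.n_cpg}\t{r.test.statistic:g}\t"
                    f"{r.test.p_value:.3g}\t{r.test.effect:.4f}\t{int(r.dm)}\n"
                )
        cats = state.get("categories", [])
        prox = {c.element_id for c in cats if c.category == "proximal"}
        dm_ids = {r.element_id for r in results if r.dm}
        tested = {r.element_id for r in results}
        a = len(dm_ids & prox)
        b = len(dm_ids - prox)
        c = len((tested - dm_ids) & prox)
        d = len(tested - dm_ids - prox)
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("dm_proximal\tdm_other\tnot_dm_proximal\tnot_dm_other\todds\tp\n")
            try:
                odds, p = methylation.fisher_enrichment([[a, b], [c, d]])
                fh.write(f"{a}\t{b}\t{c}\t{d}\t{odds:.4g}\t{p:.4g}\n")
            except ValueError:
                fh.write(f"{a}\t{b}\t{c}\t{d}\tNA\tNA\n")
        expr = state.get("expr")
        corr_path = out / "correlations.tsv"
        with open(corr_path, "w") as fh:
            fh.write("element_id\tgene_id\trho\tp_value\tsign\n")
            if expr is not None:
                cat_by_id = {c.element_id: c for c in cats}
                samples = [sid for sid, _, _ in meth.design]
                for e in em:
                    cat = cat_by_id.get(e.element_id)
                    if cat is None or cat.category != "proximal" or not cat.nearest_gene:
                        continue
                    if cat.nearest_gene not in expr.index:
                        continue
                    shared = [s for s in samples if s in e.sample_means]
                    if len(shared) < 4:
                        continue
                    mvec = [e.sample_means[s] for s in shared]
                    evec = [float(expr.loc[cat.nearest_gene, s]) for s in shared]
                    r = methylation.spearman(mvec, evec, e.element_id, cat.nearest_gene)
                    fh.write(
                        f"{r.element_id}\t{r.gene_id}\t{r.rho:.4f}\t{r.p_value:.4g}\t{r.sign}\n"
                    )
        for name in ("dm_elements.tsv", "enrichment.tsv", "correlations.tsv"):
            artifacts[name] = out / name

    manifest = {
        "version": sinescope.__version__,
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
        "stages": stages,
        "thresholds": th,
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
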