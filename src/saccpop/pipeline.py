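"""End-to-end pipeline: simulate -> call -> stats -> phylo -> karyotype -> scan.

Each stage writes plain-text outputs into the run directory; a JSON
manifest records the resolved configuration, package versions and the
SHA-256 checksum of every output, so a manifest suffices to reproduce
any run bit for bit.  All randomness derives from the single configured
seed via fixed per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from saccpop import io as spio
from saccpop import karyotype, popstats, rrhs, snpcall, synthgen
from saccpop.config import PipelineConfig
from saccpop.introscan import ReferenceLibrary, ScanParams, scan_cohort

log = logging.getLogger("saccpop")

CONSPECIFIC_TAXON = "Scerevisiae_ref"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    spec = synthgen.default_genome_spec(seed=config.seed,
                                        scale=config.genome_scale)
    params = synthgen.CohortParams(
        n_wild=config.n_wild, n_domesticated=config.n_domesticated,
        mean_depth=config.mean_depth, error_rate=config.error_rate,
        flow_noise_sd=config.flow_noise_sd)

    state: dict = {}
    for stage in ("simulate", "call", "stats", "phylo", "karyotype", "scan"):
        if stage not in config.stages:
            continue
        t = time.monotonic()
        _STAGES[stage](config, spec, params, out, state)
        log.info("stage %s finished in %.1fs", stage, time.monotonic() - t)

    manifest = {
        "config": config.to_dict(),
        "versions": _versions(),
        "outputs": _checksums(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    log.info("pipeline finished in %.1fs", time.monotonic() - t0)
    return manifest


def _stage_simulate(config, spec, params, out: Path, state: dict) -> None:
    cohort = synthgen.simulate_cohort(spec, params, seed=config.seed)
    state["cohort"] = cohort
    spio.write_fasta(out / "reference.fa",
                     {c: synthgen.seq_to_str(s)
                      for c, s in cohort.reference.items()})
    donors = {}
    taxon_rows = []
    for taxon, genome in cohort.library.genomes.items():
        for chrom, seq in genome.items():
            sid = f"{taxon}|{chrom}"
            donors[sid] = synthgen.seq_to_str(seq)
            taxon_rows.append((sid, taxon, cohort.library.tags[taxon]))
    spio.write_fasta(out / "donors.fa", donors)
    with open(out / "donor_taxa.tsv", "w") as fh:
        fh.write("seqid\ttaxon\ttag\n")
        for row in taxon_rows:
            fh.write("\t".join(row) + "\n")
    (out / "pileups").mkdir(exist_ok=True)
    (out / "genomes").mkdir(exist_ok=True)
    state["pileups"] = cohort.pileups(config.seed)
    for iid, pileup in state["pileups"].items():
        spio.write_pileup_table(out / "pileups" / f"{iid}.pileup.tsv", pileup)
        spio.write_fasta(out / "genomes" / f"{iid}.fa",
                         {c: synthgen.seq_to_str(s)
                          for c, s in cohort.isolates[iid].hapA.items()})
    cohort.flow_table().to_csv(out / "flow.tsv", sep="\t", index=False)
    spio.write_bed(out / "genes.bed", list(spec.genes))
    (out / "truth.json").write_text(cohort.truth_json())


def _stage_call(config, spec, params, out: Path, state: dict) -> None:
    pileups = state.get("pileups")
    if pileups is None:
        pdir = out / "pileups"
        if not pdir.is_dir():
            raise FileNotFoundError(
                f"stage 'call': missing pileup directory {pdir}")
        pileups = {p.name.removesuffix(".pileup.tsv"):
                   spio.read_pileup_table(p)
                   for p in sorted(pdir.glob("*.pileup.tsv"))}
        state["pileups"] = pileups
    call_params = snpcall.CallParams(
        min_depth=config.min_depth, max_depth_factor=config.max_depth_factor,
        hom_fraction=config.hom_fraction, het_fraction=config.het_fraction)
    calls = {iid: snpcall.call_pileup(pileup, params=call_params)
             for iid, pileup in pileups.items()}
    state["calls"] = calls
    matrix = snpcall.build_matrix(calls, config.max_site_missing)
    state["matrix"] = matrix
    with open(out / "matrix.tsv", "w") as fh:
        matrix.to_tsv(fh)
    if matrix.n_sites:
        with open(out / "variants.vcf", "w") as fh:
            snpcall.export_vcf(matrix, fh, spec.lengths)
    het = snpcall.heterozygosity_table(calls)
    het.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
    state["het"] = het


def _groups(state, out: Path) -> dict[str, list[str]]:
    cohort = state.get("cohort")
    if cohort is not None:
        groups: dict[str, list[str]] = {}
        for iid, truth in cohort.truths.items():
            groups.setdefault(truth.group, []).append(iid)
        return groups
    flow = pd.read_csv(out / "flow.tsv", sep="\t")
    return {g: sub["isolate"].tolist() for g, sub in flow.groupby("group")}


def _stage_stats(config, spec, params, out: Path, state: dict) -> None:
    matrix = _require_matrix(state, out)
    groups = _groups(state, out)
    calls = state.get("calls")
    rows = []
    for gid, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        invariant = 0
        if calls is not None:
            block = np.vstack([(calls[m]["call"].to_numpy() != "N")
                               for m in members])
            qualifying_total = int(
                (block.mean(axis=0) >= config.min_group_coverage).sum())
        res = popstats.nucleotide_diversity(
            matrix, members, 0, config.min_group_coverage, gid)
        if calls is not None:
            invariant = max(qualifying_total - res.n_sites_analyzed, 0)
            res = popstats.nucleotide_diversity(
                matrix, members, invariant, config.min_group_coverage, gid)
        rows.append({"group": gid, "n_isolates": len(members), "pi": res.pi,
                     "theta": res.theta, "S": res.S,
                     "sites_analyzed": res.n_sites_analyzed + invariant})
    pd.DataFrame(rows).to_csv(out / "popstats.tsv", sep="\t", index=False)

    gids = [g for g, m in sorted(groups.items()) if len(m) >= 2]
    part_rows = []
    for i in range(len(gids)):
        for j in range(i + 1, len(gids)):
            part = popstats.polymorphism_partition(
                matrix, groups[gids[i]], groups[gids[j]],
                config.partition_min_nonmissing, True,
                config.partition_mode, labels=(gids[i], gids[j]))
            try:
                frac = popstats.shared_fraction(part)
            except ValueError:
                frac = float("nan")
            part_rows.append({
                "group_a": gids[i], "group_b": gids[j],
                "shared": part.shared, "fixed": part.fixed,
                "private_a": part.private_a, "private_b": part.private_b,
                "analyzed_sites": part.analyzed_sites,
                "shared_percent": frac})
    pd.DataFrame(part_rows).to_csv(out / "partition.tsv", sep="\t",
                                   index=False)


def _stage_phylo(config, spec, params, out: Path, state: dict) -> None:
    matrix = _require_matrix(state, out)
    trees = rrhs.rrhs_trees(matrix, config.replicates, config.seed)
    trees.write(path=str(out / "replicates.nwk"), schema="newick",
                suppress_rooting=True)
    con = rrhs.consensus_from_trees(trees)
    (out / "consensus.nwk").write_text(con.newick() + "\n")


def _stage_karyotype(config, spec, params, out: Path, state: dict) -> None:
    pileups = state.get("pileups")
    if pileups is None:
        _stage_call_inputs_only(config, out, state)
        pileups = state["pileups"]
    flow = pd.read_csv(out / "flow.tsv", sep="\t") \
        if (out / "flow.tsv").exists() else None
    d_values = {} if flow is None else dict(zip(flow["isolate"], flow["D"]))
    basal = {} if flow is None else dict(zip(flow["isolate"],
                                             flow["basal_ploidy"]))
    chrom_order = [c for c, _ in spec.chromosomes]
    genes = list(spec.genes)
    chrom_rows, gene_frames = [], []
    for iid, pileup in pileups.items():
        frames = karyotype.frame_values(pileup, config.frame_size)
        D = float(d_values.get(iid, basal.get(iid, 2)))
        calls = karyotype.call_isolate(frames, chrom_order, D)
        deltas = {c.chrom: c.delta for c in calls}
        pattern = karyotype.aneuploidy_pattern(deltas, chrom_order)
        for c in calls:
            chrom_rows.append({"isolate": iid, "chrom": c.chrom,
                               "Vo": c.vo, "Va": c.va, "delta": c.delta,
                               "ambiguous": c.ambiguous, "pattern": pattern})
        gv = karyotype.gene_cnv_table(frames, genes, config.frame_size)
        gv.insert(0, "isolate", iid)
        gene_frames.append(gv)
    chrom_df = pd.DataFrame(chrom_rows)
    chrom_df.to_csv(out / "chromosome_calls.tsv", sep="\t", index=False)
    gene_df = pd.concat(gene_frames, ignore_index=True)
    thresholds = (karyotype.TailThresholds.defaults()
                  if config.tails == "default" else None)
    gene_df = karyotype.cohort_cnv_levels(gene_df, thresholds)
    gene_df.to_csv(out / "gene_cnv.tsv", sep="\t", index=False)

    groups = _groups(state, out)
    test_rows = []
    gids = sorted(groups)
    if len(gids) >= 2 and all(len(groups[g]) >= 3 for g in gids[:2]):
        ga, gb = gids[0], gids[1]
        for gene, sub in gene_df.groupby("gene"):
            va = sub[sub["isolate"].isin(groups[ga])]["value"]
            vb = sub[sub["isolate"].isin(groups[gb])]["value"]
            p, sig = karyotype.cnv_group_test(va, vb, config.cnv_test,
                                              config.cnv_alpha)
            test_rows.append({"gene": gene, "group_a": ga, "group_b": gb,
                              "p_value": p, "significant": sig})
    pd.DataFrame(test_rows).to_csv(out / "cnv_tests.tsv", sep="\t",
                                   index=False)


def _stage_scan(config, spec, params, out: Path, state: dict) -> None:
    cohort = state.get("cohort")
    if cohort is not None:
        queries = {iid: {c: synthgen.seq_to_str(s)
                         for c, s in g.hapA.items()}
                   for iid, g in cohort.isolates.items()}
        reference = {c: synthgen.seq_to_str(s)
                     for c, s in cohort.reference.items()}
        sequences = {CONSPECIFIC_TAXON: reference}
        tags = {CONSPECIFIC_TAXON: "conspecific"}
        for taxon, genome in cohort.library.genomes.items():
            sequences[taxon] = {c: synthgen.seq_to_str(s)
                                for c, s in genome.items()}
            tags[taxon] = cohort.library.tags[taxon]
    else:
        gdir = out / "genomes"
        if not gdir.is_dir():
            raise FileNotFoundError(f"stage 'scan': missing genomes {gdir}")
        queries = {p.stem: spio.read_fasta(p) for p in sorted(gdir.glob("*.fa"))}
        sequences = {CONSPECIFIC_TAXON: spio.read_fasta(out / "reference.fa")}
        tags = {CONSPECIFIC_TAXON: "conspecific"}
        donor_seqs = spio.read_fasta(out / "donors.fa")
        tax = pd.read_csv(out / "donor_taxa.tsv", sep="\t")
        for _, row in tax.iterrows():
            sequences.setdefault(row["taxon"], {})[row["seqid"]] = \
                donor_seqs[row["seqid"]]
            tags[row["taxon"]] = row["tag"]
    library = ReferenceLibrary(sequences, tags)
    sp = ScanParams(window=config.scan_window, step=config.scan_step,
                    stage1_identity=config.stage1_identity,
                    stage1_min_len=config.stage1_min_len,
                    final_identity=config.final_identity,
                    final_min_len=config.final_min_len)
    fragments = scan_cohort(queries, library, sp)
    rows = [{"fragment_id": f"frag{i + 1}", "contig": f.contig,
             "start": f.start, "end": f.end, "length": f.length,
             "mean_identity": round(f.mean_identity, 3),
             "donor": f.donor or ".", "class": f.klass,
             "carriers": ",".join(f.carriers)}
            for i, f in enumerate(fragments)]
    pd.DataFrame(rows, columns=["fragment_id", "contig", "start", "end",
                                "length", "mean_identity", "donor", "class",
                                "carriers"]).to_csv(
        out / "fragments.tsv", sep="\t", index=False)


def _stage_call_inputs_only(config, out: Path, state: dict) -> None:
    pdir = out / "pileups"
    if not pdir.is_dir():
        raise FileNotFoundError(f"missing pileup directory {pdir}")
    state["pileups"] = {p.name.removesuffix(".pileup.tsv"):
                        spio.read_pileup_table(p)
                        for p in sorted(pdir.glob("*.pileup.tsv"))}


def _require_matrix(state: dict, out: Path):
    matrix = state.get("matrix")
    if matrix is None:
        path = out / "matrix.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing genotype matrix {path}")
        with open(path) as fh:
            matrix = snpcall.GenotypeMatrix.from_tsv(fh)
        state["matrix"] = matrix
    return matrix


_STAGES = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "stats": _stage_stats,
    "phylo": _stage_phylo,
    "karyotype": _stage_karyotype,
    "scan": _stage_scan,
}


def _versions() -> dict[str, str]:
    import dendropy
    import scipy

    import saccpop

    return {"saccpop": saccpop.__version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "dendropy": dendropy.__version__,
            "python": sys.version.split()[0]}


def _checksums(out: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            sums[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return sums
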