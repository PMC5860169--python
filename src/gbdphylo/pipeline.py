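"""End-to-end orchestration and command-line interface.

``run``      genomes -> distance matrix (+replicates) -> support tree ->
             per-rank clusters (+ taxon-support report when a taxonomy is
             supplied), all seeded and logged.
``grid``     evaluate the settings grid against a taxonomy and flag the
             two-step Pareto selection.
``simulate`` write a synthetic dataset (FASTA, true tree, taxonomy, hosts).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import sys
import tempfile
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, cluster, config, formats, gbdp, phylo, studyops, synthetic
from .alignment import AMINO_ACID, NUCLEOTIDE
from .errors import GBDPError

logger = logging.getLogger("gbdphylo")

MODE_TO_TYPE = {"nt": NUCLEOTIDE, "aa": AMINO_ACID}
SERVICE_CAP = 100  # warn above this many genomes


def _load_genomes(paths, seq_type):
    genomes = [formats.read_fasta(p, seq_type) for p in paths]
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise GBDPError(f"duplicate genome ids among inputs: {sorted(ids)}")
    return sorted(genomes, key=lambda g: g.genome_id)


def infer_support_tree(matrix: gbdp.DistanceMatrix):
    """Midpoint-rooted NJ tree with pseudo-bootstrap branch support."""
    tree = phylo.midpoint_root(phylo.nj_tree(matrix))
    replicate_trees = [
        phylo.nj_tree(gbdp.DistanceMatrix(matrix.labels, rep))
        for rep in matrix.replicates
    ]
    return phylo.branch_support(tree, replicate_trees)


def run_analysis(
    genomes,
    settings: gbdp.GBDPSettings,
    outdir: Path,
    taxonomy: pd.DataFrame | None = None,
    thresholds: dict | None = None,
    linkage_f: float = config.DEFAULT_F,
    incomplete_ids: tuple[str, ...] = (),
    write_replicates: bool = True,
) -> dict:
    """Compute and write the full artifact bundle; returns artifact paths."""
    if len(genomes) > SERVICE_CAP:
        logger.warning(
            "%d genomes exceed the recommended cap of %d; proceeding anyway",
            len(genomes), SERVICE_CAP,
        )
    if incomplete_ids and settings.formula in ("d0", "d6"):
        logger.warning(
            "genomes flagged incomplete (%s) with formula %s; formula d4 is "
            "robust to incomplete genomes and is recommended instead",
            ",".join(incomplete_ids), settings.formula,
        )
    thresholds = thresholds or config.DEFAULT_THRESHOLDS[settings.seq_type]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    try:
        matrix = gbdp.build_matrix(genomes, settings)
        mpath = outdir / "distances.phylip"
        formats.write_phylip_matrix(matrix.labels, matrix.values, mpath)
        artifacts["matrix"] = mpath
        if write_replicates:
            for r, rep in enumerate(matrix.replicates):
                rpath = outdir / f"distances_rep{r:03d}.phylip"
                formats.write_phylip_matrix(matrix.labels, rep, rpath)
        tree = infer_support_tree(matrix)
        tpath = outdir / "tree.nwk"
        formats.write_newick(tree, tpath)
        artifacts["tree"] = tpath

        cluster_rows = {g.genome_id: {} for g in genomes}
        summary_rows = []
        for rank, T in thresholds.items():
            part = cluster.threshold_cluster(matrix, T, linkage_f)
            for gid, lab in part.items():
                cluster_rows[gid][rank] = lab
            summary_rows.append(
                dict(rank=rank, T=T, F=linkage_f, n_clusters=len(set(part.values())))
            )
        cframe = pd.DataFrame(
            [dict(genome_id=gid, **ranks) for gid, ranks in sorted(cluster_rows.items())]
        )
        cpath = outdir / "clusters.tsv"
        cframe.to_csv(cpath, sep="\t", index=False)
        artifacts["clusters"] = cpath
        pd.DataFrame(summary_rows).to_csv(
            outdir / "cluster_summary.tsv", sep="\t", index=False
        )

        if taxonomy is not None:
            reports = []
            for rank in ("species", "genus", "subfamily", "family"):
                try:
                    rep = phylo.taxon_support(tree, taxonomy, rank)
                except GBDPError as exc:
                    logger.warning("taxon support skipped at %s: %s", rank, exc)
                    continue
                frame = rep.to_frame()
                frame["overall"] = rep.overall
                reports.append(frame)
            if reports:
                spath = outdir / "taxon_support.tsv"
                pd.concat(reports).to_csv(spath, sep="\t", index=False)
                artifacts["taxon_support"] = spath

        with open(outdir / "run.log", "w") as fh:
            fh.write(f"gbdphylo {__version__}\n")
            fh.write(f"numpy {np.__version__}\n")
            fh.write(f"settings {settings}\n")
            fh.write(f"seed {settings.seed}\n")
            fh.write(f"thresholds {thresholds}\n")
            fh.write(f"F {linkage_f}\n")
            fh.write(f"genomes {[g.genome_id for g in genomes]}\n")
    except Exception:
        shutil.rmtree(outdir, ignore_errors=True)
        raise
    return artifacts


def evaluate_grid(
    genomes_by_type: dict,
    taxonomy: pd.DataFrame,
    all_formulas: bool = False,
    n_replicates: int = 100,
    seed: int = 0,
    linkage_f: float = config.DEFAULT_F,
) -> pd.DataFrame:
    """Score every grid point (taxon support + MRI per rank) and flag the
    two-step Pareto selection.

    HSP lists are computed once per (pair, seq_type) at the loosest e-value
    and re-filtered per grid point.
    """
    populated = [
        r for r in studyops.OBJECTIVE_RANKS if (taxonomy[r] != "").any()
    ]
    if len(populated) < 2:
        raise GBDPError("taxonomy must populate at least two ranks")
    from .alignment import find_hsps

    scores = []
    for seq_type, genomes in genomes_by_type.items():
        cache = {}
        base = gbdp.GBDPSettings(seq_type=seq_type, evalue_max=10.0)
        scheme = base.scheme()
        for i, ga in enumerate(genomes):
            for gb in genomes[i + 1 :]:
                cache[(ga.genome_id, gb.genome_id)] = find_hsps(
                    ga, gb, scheme, evalue_max=10.0
                )
        for settings in studyops.settings_grid(all_formulas, n_replicates, seed):
            if settings.seq_type != seq_type:
                continue
            pair_hsps = {
                key: [h for h in hsps if h.evalue <= settings.evalue_max]
                for key, hsps in cache.items()
            }
            matrix = gbdp.build_matrix(genomes, settings, pair_hsps=pair_hsps)
            tree = infer_support_tree(matrix)
            ts, mri_vals = {}, {}
            for rank in studyops.OBJECTIVE_RANKS:
                ts[rank] = phylo.taxon_support(tree, taxonomy, rank).overall
                _, best_mri, _ = cluster.rank_pipeline(
                    matrix, taxonomy, rank, F=linkage_f
                )
                mri_vals[rank] = best_mri
            scores.append(
                studyops.SettingsScore(settings=settings, taxon_support=ts, mri=mri_vals)
            )
    return studyops.scores_frame(scores)


# --------------------------------------------------------------------------
# external alignment backend


def external_hsps(genomes, seq_type, workdir=None):
    """Shell out to an external local-alignment tool (BLAST+) and read its
    12-column tabular output; returns {(query_id, subject_id): [HSP, ...]}."""
    prog = "blastn" if seq_type == NUCLEOTIDE else "blastp"
    dbtype = "nucl" if seq_type == NUCLEOTIDE else "prot"
    out = {}
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        for g in genomes:
            formats.write_fasta(g, tmp / f"{g.genome_id}.fasta")
        for ga in genomes:
            for gb in genomes:
                if ga.genome_id == gb.genome_id:
                    continue
                db = tmp / f"{gb.genome_id}.db"
                if not (tmp / f"{gb.genome_id}.db.made").exists():
                    subprocess.run(
                        ["makeblastdb", "-in", str(tmp / f"{gb.genome_id}.fasta"),
                         "-dbtype", dbtype, "-out", str(db)],
                        check=True, capture_output=True,
                    )
                    (tmp / f"{gb.genome_id}.db.made").touch()
                hits = tmp / "hits.tsv"
                subprocess.run(
                    [prog, "-query", str(tmp / f"{ga.genome_id}.fasta"),
                     "-db", str(db), "-outfmt", "6", "-out", str(hits)],
                    check=True, capture_output=True,
                )
                raw = formats.read_alignment_tab(hits)
                # tabular hits carry record ids; re-key to genome ids
                from dataclasses import replace as _replace

                out[(ga.genome_id, gb.genome_id)] = [
                    _replace(h, query_id=ga.genome_id, subject_id=gb.genome_id)
                    for h in raw
                ]
    return out


# --------------------------------------------------------------------------
# CLI


@click.group()
@click.version_option(version=__version__)
def main():
    """Genome BLAST distance phylogeny and classification of prokaryotic
    viruses."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(message)s")


@main.command("run")
@click.argument("fastas", nargs=-1, type=click.Path(exists=True), required=True)
@click.option("--mode", type=click.Choice(["nt", "aa"]), default="nt")
@click.option("--formula", type=click.Choice(sorted(gbdp.FORMULAS)), default=None)
@click.option("--algorithm", type=click.Choice(gbdp.ALGORITHMS), default="trimming")
@click.option("--evalue", type=float, default=None)
@click.option("--word-length", type=int, default=None)
@click.option("--replicates", type=int, default=100)
@click.option("--f", "linkage_f", type=float, default=config.DEFAULT_F)
@click.option("--t-species", type=float, default=None)
@click.option("--t-genus", type=float, default=None)
@click.option("--t-subfamily", type=float, default=None)
@click.option("--t-family", type=float, default=None)
@click.option("--seed", type=int, default=0)
@click.option("--taxonomy", type=click.Path(exists=True), default=None)
@click.option("--incomplete-ids", default="",
              help="comma-separated genome ids with incomplete sequences")
@click.option("--no-replicate-files", is_flag=True, default=False)
@click.option("--outdir", type=click.Path(), required=True)
def cli_run(fastas, mode, formula, algorithm, evalue, word_length, replicates,
            linkage_f, t_species, t_genus, t_subfamily, t_family, seed,
            taxonomy, incomplete_ids, no_replicate_files, outdir):
    """Distances, support tree and taxon-boundary suggestions for genomes."""
    seq_type = MODE_TO_TYPE[mode]
    try:
        if len(fastas) < 2:
            raise GBDPError("need at least two genome FASTA files")
        genomes = _load_genomes(fastas, seq_type)
        defaults = config.default_settings(seq_type, seed=seed,
                                           n_replicates=replicates)
        settings = gbdp.GBDPSettings(
            seq_type=seq_type,
            word_length=word_length or defaults.effective_word_length,
            evalue_max=evalue if evalue is not None else defaults.evalue_max,
            algorithm=algorithm,
            formula=formula or defaults.formula,
            n_replicates=replicates,
            seed=seed,
        )
        thresholds = dict(config.DEFAULT_THRESHOLDS[seq_type])
        for rank, val in (("species", t_species), ("genus", t_genus),
                          ("subfamily", t_subfamily), ("family", t_family)):
            if val is not None:
                thresholds[rank] = val
        tax = formats.read_taxonomy(taxonomy) if taxonomy else None
        inc = tuple(x for x in incomplete_ids.split(",") if x)
        run_analysis(genomes, settings, Path(outdir), taxonomy=tax,
                     thresholds=thresholds, linkage_f=linkage_f,
                     incomplete_ids=inc,
                     write_replicates=not no_replicate_files)
        logger.info("settings: %s", settings)
    except GBDPError as exc:
        raise click.ClickException(str(exc))


@main.command("grid")
@click.option("--nt-dir", type=click.Path(exists=True), default=None,
              help="directory of nucleotide genome FASTAs")
@click.option("--aa-dir", type=click.Path(exists=True), default=None,
              help="directory of proteome FASTAs")
@click.option("--taxonomy", type=click.Path(exists=True), required=True)
@click.option("--all-formulas", is_flag=True, default=False)
@click.option("--replicates", type=int, default=100)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True)
def cli_grid(nt_dir, aa_dir, taxonomy, all_formulas, replicates, seed, out):
    """Evaluate the settings grid and flag the Pareto selection."""
    try:
        genomes_by_type = {}
        if nt_dir:
            paths = sorted(Path(nt_dir).glob("*.fasta"))
            genomes_by_type[NUCLEOTIDE] = _load_genomes(paths, NUCLEOTIDE)
        if aa_dir:
            paths = sorted(Path(aa_dir).glob("*.fasta"))
            genomes_by_type[AMINO_ACID] = _load_genomes(paths, AMINO_ACID)
        if not genomes_by_type:
            raise GBDPError("provide --nt-dir and/or --aa-dir")
        tax = formats.read_taxonomy(taxonomy)
        frame = evaluate_grid(genomes_by_type, tax, all_formulas=all_formulas,
                              n_replicates=replicates, seed=seed)
        frame.to_csv(out, sep="\t", index=False)
    except GBDPError as exc:
        raise click.ClickException(str(exc))


@main.command("simulate")
@click.option("--n-taxa", type=int, default=8)
@click.option("--shape", type=click.Choice(["balanced", "caterpillar", "random"]),
              default="balanced")
@click.option("--length", type=int, default=20_000)
@click.option("--seed", type=int, default=0)
@click.option("--outdir", type=click.Path(), required=True)
def cli_simulate(n_taxa, shape, length, seed, outdir):
    """Write a synthetic dataset with known tree and taxonomy."""
    spec = synthetic.SimulationSpec(
        n_taxa=n_taxa, tree_shape=shape, genome_length=length, seed=seed
    )
    tree, genomes, taxonomy, hosts = synthetic.simulate_dataset(spec)
    outdir = Path(outdir)
    (outdir / "nt").mkdir(parents=True, exist_ok=True)
    (outdir / "aa").mkdir(parents=True, exist_ok=True)
    for g in genomes:
        formats.write_fasta(g, outdir / "nt" / f"{g.genome_id}.fasta")
        formats.write_fasta(synthetic.to_proteome(g, spec.protein_block),
                            outdir / "aa" / f"{g.genome_id}.fasta")
    formats.write_newick(tree, outdir / "true_tree.nwk")
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    hosts.to_csv(outdir / "hosts.tsv", sep="\t", index=False)


if __name__ == "__main__":  # pragma: no cover
    main()
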