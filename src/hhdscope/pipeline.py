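"""End-to-end pipeline: simulate, screen, cluster, compare, profile.

Runs the stages in dependency order on a synthetic benchmark (or on
user-supplied inputs), writing each stage's outputs into its own
directory together with a run manifest of parameters and checksums.
Stage defaults are the analysis constants used throughout the package:
domain hits kept at E < 1e-5; the similarity network thresholded at
E <= 1e-4 with -log10 weights; clustering coverage 0.8; redundancy
reduction at 70% (92% fallback when a cluster collapses to a single
representative); conservation thresholds 80% representation / 75%
group conservation; alignment gap filters 90% (columns) then 20%
(sequences).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, communities, conservation, phylogeny, variants
from .core_io import Msa, Sequence, newick_string, write_fasta, write_tsv
from .pairwise_align import SubstitutionMatrix, all_vs_all, calibrate_karlin
from .profile_hmm import (
    ProfileHmm, build_profile, calibrate, extract_hit_sequences, search,
    viterbi_path,
)
from .synthetic_data import Benchmark, default_benchmark, write_benchmark

logger = logging.getLogger("hhdscope.pipeline")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline thresholds, stage toggles and the master seed."""

    seed: int = 42
    # synthetic benchmark
    n_families: int = 5
    n_seqs_per_family: int = 40
    n_decoys: int = 500
    # profile screening
    e_threshold: float = 1e-5
    hmm_calibration_decoys: int = 5000
    # similarity network
    e_cutoff: float = 1e-4
    # clustering
    identity_threshold: float = 0.45
    coverage_threshold: float = 0.8
    threshold_step: float = 0.01
    min_cluster_frac: float = 0.05
    split_frac: float = 0.10
    # redundancy / phylogeny
    redundancy_identity: float = 0.70
    redundancy_fallback: float = 0.92
    n_bootstrap: int = 1000
    # conservation
    represent_threshold: float = 0.80
    conserve_threshold: float = 0.75
    max_col_gap: float = 0.90
    max_seq_gap: float = 0.20
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "profile", "allvsall", "cluster", "communities",
        "tree", "conserve", "variants",
    ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def profile_align(hmm: ProfileHmm, seqs: list[Sequence]) -> tuple[Msa, list[int]]:
    """Align sequences to the profile's match states.

    Each sequence's Viterbi path places residues on match states (delete
    states leave gaps, insert-state residues are dropped), producing a
    fixed-width alignment on the profile frame. The accompanying column
    numbers carry each match state's seed-alignment column, i.e. the
    master coordinate frame.
    """
    k = hmm.n_match_states
    members = []
    for seq in seqs:
        row = ["-"] * k
        path, _ = viterbi_path(hmm, seq.residues)
        for state, i, j in path:
            if state == "M":
                row[j - 1] = seq.residues[i - 1]
        members.append(Sequence(seq.id, "".join(row), taxon=seq.taxon))
    return Msa(members), list(hmm.column_map)


@dataclass
class PipelineResult:
    """In-memory handles to everything a full run produced."""

    config: PipelineConfig
    benchmark: Benchmark
    hmm: ProfileHmm
    hits: list
    domain_seqs: list[Sequence]
    scores: pd.DataFrame
    partition: clustering.Partition
    trace: clustering.ClusterTrace
    community: communities.CommunityAssignment
    supported_tree: phylogeny.SupportedTree | None
    profiles: dict[str, conservation.ConservationProfile]
    pair_reports: dict[str, list]
    variant_table: pd.DataFrame | None
    manifest: dict


def synthetic_variant_table(
    benchmark: Benchmark, hits, n_variants: int = 10, seed: int = 0,
    fraction_outside: float = 0.6,
) -> pd.DataFrame:
    """Random missense variants against the simulated proteins.

    A fraction falls inside detected domain envelopes (mappable), the
    rest in the flanks; ref residues are read off the true protein
    sequences so mapping round-trips are exact.
    """
    rng = np.random.default_rng([seed, 509])
    by_id = {s.id: s for s in benchmark.database}
    domain_hits = [h for h in hits if h.target_id in by_id]
    rows = []
    n_inside = round(n_variants * (1 - fraction_outside))
    for i in range(n_variants):
        h = domain_hits[int(rng.integers(len(domain_hits)))]
        protein = by_id[h.target_id]
        if i < n_inside:
            pos = int(rng.integers(h.start, h.end + 1))
        else:  # flank position, strictly outside every envelope
            for _ in range(100):
                pos = int(rng.integers(1, len(protein.residues) + 1))
                if not any(x.start <= pos <= x.end for x in domain_hits
                           if x.target_id == protein.id):
                    break
        ref = protein.residues[pos - 1]
        alt = "AVLIKRDE".replace(ref, "")[int(rng.integers(0, 6))]
        rows.append({
            "protein_id": protein.id, "ref": ref, "pos": pos, "alt": alt,
            "classification": "VUS" if rng.random() < 0.9 else "pathogenic",
        })
    return pd.DataFrame(rows)


def run(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the configured stages in dependency order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yml")
    manifest: dict = {"stages": {}, "seed": config.seed}
    t_start = time.time()

    def record(stage: str, outputs: dict[str, Path], params: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p), "sha256": _checksum(p)}
                        for k, p in outputs.items()},
            "params": params,
            "elapsed_s": round(time.time() - t_start, 2),
        }

    enabled = set(config.stages)

    # --- simulate -----------------------------------------------------
    if "simulate" not in enabled:
        raise DependencyError("pipeline currently requires the simulate stage")
    stage_dir = outdir / "simulate"
    bench = default_benchmark(
        seed=config.seed, n_families=config.n_families,
        n_seqs=config.n_seqs_per_family, n_decoys=config.n_decoys,
    )
    paths = write_benchmark(bench, stage_dir)
    record("simulate", paths, {"seed": config.seed,
                               "n_families": config.n_families,
                               "n_seqs": config.n_seqs_per_family,
                               "n_decoys": config.n_decoys})

    # --- profile build + search --------------------------------------
    if "profile" not in enabled:
        raise DependencyError("downstream stages need the profile stage")
    stage_dir = outdir / "profile"
    stage_dir.mkdir(exist_ok=True)
    hmm = build_profile(bench.seed_msa)
    median_len = int(np.median([len(s.residues) for s in bench.database]))
    calibrate(hmm, n_decoys=config.hmm_calibration_decoys,
              decoy_length=median_len, seed=config.seed)
    hmm.to_json(stage_dir / "model.json")
    hits = search(hmm, bench.database, config.e_threshold)
    write_tsv(
        [{"target": h.target_id, "start": h.start, "end": h.end,
          "bits": h.bit_score, "evalue": f"{h.e_value:.3g}"} for h in hits],
        stage_dir / "hits.tsv",
        ["target", "start", "end", "bits", "evalue"],
    )
    domain_seqs = extract_hit_sequences(hits, bench.database)
    write_fasta(domain_seqs, stage_dir / "domains.fasta")
    record("profile", {"model": stage_dir / "model.json",
                       "hits": stage_dir / "hits.tsv",
                       "domains": stage_dir / "domains.fasta"},
           {"e_threshold": config.e_threshold,
            "calibration_decoys": config.hmm_calibration_decoys})

    # --- all-vs-all ----------------------------------------------------
    stage_dir = outdir / "allvsall"
    stage_dir.mkdir(exist_ok=True)
    matrix = SubstitutionMatrix()
    karlin = calibrate_karlin(matrix, seed=config.seed, n_decoys=1000)
    scores = all_vs_all(domain_seqs, matrix, karlin)
    scores.to_csv(stage_dir / "scores.tsv", sep="\t", index=False)
    record("allvsall", {"scores": stage_dir / "scores.tsv"},
           {"matrix": matrix.name, "gap_open": matrix.gap_open,
            "gap_extend": matrix.gap_extend})

    # --- clustering ----------------------------------------------------
    ids = [s.id for s in domain_seqs]
    stage_dir = outdir / "cluster"
    stage_dir.mkdir(exist_ok=True)
    partition = clustering.identity_graph_partition(
        ids, scores, config.identity_threshold, config.coverage_threshold
    )
    write_tsv(
        [{"id": sid, "cluster": label} for sid, label in partition.assignment.items()],
        stage_dir / "assignment.tsv", ["id", "cluster"],
    )
    trace = clustering.incremental_partition(
        ids, scores, config.threshold_step, config.min_cluster_frac,
        config.split_frac, config.coverage_threshold,
    )
    hit_family = {}
    for r in bench.truth.rows:
        for sid in ids:
            if sid.startswith(f"prot_{r.member_id}/"):
                hit_family[sid] = r.family
    trace.annotate(hit_family)
    trace.to_json(stage_dir / "trace.json")
    record("cluster", {"assignment": stage_dir / "assignment.tsv",
                       "trace": stage_dir / "trace.json"},
           {"identity_threshold": config.identity_threshold,
            "coverage_threshold": config.coverage_threshold,
            "threshold_step": config.threshold_step})

    # --- communities ---------------------------------------------------
    stage_dir = outdir / "communities"
    stage_dir.mkdir(exist_ok=True)
    graph = communities.build_adjacency(scores, config.e_cutoff, ids=ids)
    assignment = communities.louvain(graph, seed=config.seed)
    write_tsv(
        [{"id": sid, "community": c} for sid, c in assignment.assignment.items()],
        stage_dir / "communities.tsv", ["id", "community"],
    )
    order, mat, boundaries = communities.heatmap_order(scores, assignment)
    pd.DataFrame(mat, index=order, columns=order).to_csv(
        stage_dir / "heatmap_matrix.tsv", sep="\t"
    )
    (stage_dir / "communities.json").write_text(json.dumps({
        "modularity": assignment.modularity, "seed": assignment.seed,
        "n_communities": len(assignment.communities()),
        "block_boundaries": boundaries,
    }, indent=1))
    record("communities", {"communities": stage_dir / "communities.tsv",
                           "matrix": stage_dir / "heatmap_matrix.tsv",
                           "summary": stage_dir / "communities.json"},
           {"e_cutoff": config.e_cutoff})

    # --- master-frame alignment of all hits (needed by tree & conserve)
    master_msa, master_columns = profile_align(hmm, domain_seqs)

    # --- phylogeny ------------------------------------------------------
    supported = None
    if "tree" in enabled:
        stage_dir = outdir / "tree"
        stage_dir.mkdir(exist_ok=True)
        reps: list[Sequence] = []
        for label, members in partition.clusters().items():
            cluster_seqs = [s for s in domain_seqs if s.id in set(members)]
            if len(cluster_seqs) < 2:
                continue
            cluster_reps, _ = clustering.reduce_redundancy(
                cluster_seqs, config.redundancy_identity
            )
            if len(cluster_reps) < 2:  # highly conserved cluster: relax
                cluster_reps, _ = clustering.reduce_redundancy(
                    cluster_seqs, config.redundancy_fallback
                )
            reps.extend(cluster_reps[:6])
        rep_ids = {s.id for s in reps}
        rep_msa = Msa([m for m in master_msa.members if m.id in rep_ids])
        ref_tree = phylogeny.nj_tree(rep_msa, correction="poisson")
        replicates = phylogeny.bootstrap_trees(
            rep_msa, config.n_bootstrap, seed=config.seed, correction="poisson"
        )
        supported = phylogeny.tbe_support(ref_tree, replicates)
        outgroup = {s.id for s in reps if hit_family.get(s.id) == bench.specs[0].name}
        try:
            rooted = phylogeny.root_between(supported.tree, outgroup)
        except phylogeny.RootingError as exc:
            logger.warning("rooting failed: %s", exc)
            rooted = supported.tree
        from .core_io import write_newick
        write_newick(rooted, stage_dir / "tree.nwk")
        write_tsv(
            [{"bipartition": "|".join(sorted(s.bipartition)),
              "size": s.light_side_size,
              "fbp": round(s.fbp, 4), "tbe": round(s.tbe, 4)}
             for s in supported.supports],
            stage_dir / "supports.tsv", ["bipartition", "size", "fbp", "tbe"],
        )
        record("tree", {"tree": stage_dir / "tree.nwk",
                        "supports": stage_dir / "supports.tsv"},
               {"n_bootstrap": config.n_bootstrap,
                "redundancy_identity": config.redundancy_identity})

    # --- conservation ---------------------------------------------------
    profiles: dict[str, conservation.ConservationProfile] = {}
    pair_reports: dict[str, list] = {}
    if "conserve" in enabled:
        stage_dir = outdir / "conserve"
        stage_dir.mkdir(exist_ok=True)
        profile_rows_all, pair_rows, set_rows = [], [], []
        for label, members in partition.clusters().items():
            if len(members) < 5:
                continue
            sub = Msa([m for m in master_msa.members if m.id in set(members)])
            filtered, _ = conservation.filter_alignment(
                sub, config.max_col_gap, config.max_seq_gap
            )
            kept = [master_columns[i] for i, keep in enumerate(
                _kept_columns(sub, config.max_col_gap)) if keep]
            nr, _ = clustering.reduce_redundancy(filtered.members, 0.95)
            nr_msa = Msa(nr) if len(nr) >= 3 else filtered
            prof = conservation.conservation_profile(
                nr_msa, config.represent_threshold, config.conserve_threshold,
                column_numbers=kept[: nr_msa.n_cols],
            )
            name = f"cluster_{label}"
            profiles[name] = prof
            pair_reports[name] = conservation.detect_pairs(prof)
            for row in conservation.profile_rows(prof):
                profile_rows_all.append({"cluster": name, **row})
            for rep in pair_reports[name]:
                pair_rows.append({
                    "cluster": name, "pair": f"{rep.pair[0]}-{rep.pair[1]}",
                    "status": rep.status,
                })
            for set_name in conservation.POSITION_SETS:
                try:
                    got, size = conservation.score_position_set(prof, set_name)
                    set_rows.append({"cluster": name, "set": set_name,
                                     "conserved": got, "size": size})
                except conservation.CoordinateError:
                    set_rows.append({"cluster": name, "set": set_name,
                                     "conserved": "", "size": ""})
        write_tsv(profile_rows_all, stage_dir / "profiles.tsv",
                  ["cluster", "column", "representation", "group", "frequency", "class"])
        write_tsv(pair_rows, stage_dir / "pairs.tsv", ["cluster", "pair", "status"])
        write_tsv(set_rows, stage_dir / "position_sets.tsv",
                  ["cluster", "set", "conserved", "size"])
        record("conserve", {"profiles": stage_dir / "profiles.tsv",
                            "pairs": stage_dir / "pairs.tsv",
                            "position_sets": stage_dir / "position_sets.tsv"},
               {"represent_threshold": config.represent_threshold,
                "conserve_threshold": config.conserve_threshold})

    # --- variants --------------------------------------------------------
    variant_df = None
    if "variants" in enabled:
        stage_dir = outdir / "variants"
        stage_dir.mkdir(exist_ok=True)
        table = synthetic_variant_table(bench, hits, n_variants=10,
                                        seed=config.seed)
        context = {}
        prof_of = {}
        cluster_of = {sid: f"cluster_{label}"
                      for sid, label in partition.assignment.items()}
        for h in hits:
            key = f"{h.target_id}/{h.start}-{h.end}"
            if key in {m.id for m in master_msa.members}:
                context[key] = (master_msa, key, master_columns)
                prof_of[key] = cluster_of.get(key, "")
        variant_df, summary = variants.batch_annotate(
            table, hits, context, profiles, prof_of
        )
        variant_df.to_csv(stage_dir / "variants_annotated.tsv", sep="\t",
                          index=False)
        (stage_dir / "summary.json").write_text(json.dumps(
            {k: v for k, v in summary.items() if k != "errors"}, indent=1))
        record("variants", {"annotated": stage_dir / "variants_annotated.tsv",
                            "summary": stage_dir / "summary.json"},
               {"n_variants": len(table)})

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(
        config=config, benchmark=bench, hmm=hmm, hits=hits,
        domain_seqs=domain_seqs, scores=scores, partition=partition,
        trace=trace, community=assignment, supported_tree=supported,
        profiles=profiles, pair_reports=pair_reports,
        variant_table=variant_df, manifest=manifest,
    )


def _kept_columns(msa: Msa, max_col_gap: float) -> list[bool]:
    """Mask of columns surviving the gap filter (for renumbering)."""
    mat = np.array([list(m.residues) for m in msa.members])
    return ((mat == "-").mean(axis=0) <= max_col_gap).tolist()
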