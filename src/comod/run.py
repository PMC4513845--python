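"""The optimization loop and the results store.

A run seeds overlapping memberships and then iterates: compute the active
score matrices (expression every iteration; network and set enrichment when
scheduled; motif discovery on its own, sparser schedule with the discovered
PSSMs cached in between), standardize and combine them, add annealed noise,
convert to kernel-CDF membership probabilities, and offer a random half of
the genes and conditions one membership swap each.  Per-iteration summary
statistics and everything needed to reproduce the run bit-for-bit (config,
seed, code version) are kept in the results store, which serializes to a
directory holding an SQLite database, TSV rosters, a JSON config snapshot
and MEME-format motif text.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combine import anneal_noise, combine_scores, kernel_membership_probs
from .config import RunConfig
from .expression import condition_scores, row_expression_scores
from .evaluate import mean_squared_residue
from .io import (AssociationNetwork, ExpressionMatrix, GeneSetCollection,
                 PromoterSet)
from .membership import MembershipState, apply_moves, default_k, seed_memberships
from .motifs import (MotifModel, background_frequencies, batch_score_clusters,
                     make_backend, motif_row_scores, shuffled_null,
                     _group_onehot)
from .network import network_scores
from .scores import ScoreMatrix
from .sets import set_enrichment_row_scores


@dataclass
class ResultsStore:
    config: RunConfig
    state: MembershipState
    stats: pd.DataFrame
    cluster_motifs: dict[int, list[MotifModel]] = field(default_factory=dict)
    version: str = __version__

    def rosters(self) -> list[dict]:
        out = []
        for j in range(self.state.k):
            out.append({"cluster": j,
                        "genes": self.state.gene_roster(j),
                        "conditions": self.state.condition_roster(j)})
        return out

    def gene_clusters(self) -> list[set[str]]:
        return [set(r["genes"]) for r in self.rosters()]

    # -- serialization ------------------------------------------------------

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(
            {"version": self.version, "seed": self.config.rng_seed,
             "config": json.loads(self.config.to_json())}, indent=2))
        self.stats.to_csv(out / "stats.tsv", sep="\t", index=False)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("cluster\tkind\tmember\n")
            for r in self.rosters():
                for g in r["genes"]:
                    fh.write(f"{r['cluster']}\tgene\t{g}\n")
                for c in r["conditions"]:
                    fh.write(f"{r['cluster']}\tcondition\t{c}\n")
        write_meme_motifs(self.cluster_motifs, out / "motifs.meme")
        db = out / "results.db"
        if db.exists():
            db.unlink()
        con = sqlite3.connect(db)
        try:
            con.execute("CREATE TABLE run_info (key TEXT, value TEXT)")
            con.executemany("INSERT INTO run_info VALUES (?, ?)",
                            [("version", self.version),
                             ("seed", str(self.config.rng_seed)),
                             ("k", str(self.state.k)),
                             ("config", self.config.to_json())])
            self.stats.to_sql("stats", con, index=False)
            rows = [(r["cluster"], "gene", g)
                    for r in self.rosters() for g in r["genes"]]
            rows += [(r["cluster"], "condition", c)
                     for r in self.rosters() for c in r["conditions"]]
            con.execute("CREATE TABLE members (cluster INT, kind TEXT, member TEXT)")
            con.executemany("INSERT INTO members VALUES (?, ?, ?)", rows)
            con.commit()
        finally:
            con.close()
        return out

    @staticmethod
    def load_rosters(out_dir: str | Path) -> list[dict]:
        con = sqlite3.connect(Path(out_dir) / "results.db")
        try:
            df = pd.read_sql("SELECT * FROM members", con)
        finally:
            con.close()
        out = []
        for j in sorted(df["cluster"].unique()):
            sub = df[df["cluster"] == j]
            out.append({
                "cluster": int(j),
                "genes": sorted(sub.loc[sub["kind"] == "gene", "member"]),
                "conditions": sorted(sub.loc[sub["kind"] == "condition", "member"]),
            })
        return out

    @staticmethod
    def load_stats(out_dir: str | Path) -> pd.DataFrame:
        con = sqlite3.connect(Path(out_dir) / "results.db")
        try:
            return pd.read_sql("SELECT * FROM stats", con)
        finally:
            con.close()


def write_meme_motifs(cluster_motifs: dict[int, list[MotifModel]],
                      path: str | Path) -> None:
    """Write discovered PSSMs in minimal MEME motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
                 "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for j in sorted(cluster_motifs):
            for idx, m in enumerate(cluster_motifs[j]):
                fh.write(f"MOTIF cluster{j}_m{idx} {m.consensus}\n")
                fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                         f"nsites= {max(len(m.sites), 1)} E= {m.evalue:.3g}\n")
                for row in m.pssm:
                    fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
                fh.write("\n")


def _motif_weight(iteration: int, total: int, ramp_end: float) -> float:
    """Linear ramp 0 -> 1 reaching 1 at ramp_end * total, then constant."""
    end = max(1.0, ramp_end * total)
    return float(min(1.0, iteration / end))


def run(expr: ExpressionMatrix, config: RunConfig | None = None,
        promoters: PromoterSet | None = None,
        networks: list[AssociationNetwork] | None = None,
        sets: GeneSetCollection | None = None,
        progress: bool = False) -> ResultsStore:
    """Execute a full biclustering run; expression data alone is sufficient."""
    config = config or RunConfig()
    networks = networks or []
    k = config.k if config.k is not None else default_k(expr.n_genes, config.v)
    rng = np.random.default_rng(config.rng_seed)
    state = seed_memberships(expr.gene_ids, expr.condition_ids, k, config.v, rng)

    # scorers activate only when their inputs were supplied; external motif
    # backends are probed here so a missing binary fails before the loop
    backend = None
    gene_seqs: dict[str, str] = {}
    if config.motif_backend != "none" and promoters is not None \
            and config.scorer_entry("motif") is not None:
        for g in expr.gene_ids:
            seq = promoters.get(g, config.operon_map)
            if seq is not None:
                gene_seqs[g] = seq
        backend = make_backend(
            config.motif_backend,
            background=gene_seqs if config.motif_backend == "internal" else None,
            **({"min_width": config.motif_min_width,
                "max_width": config.motif_max_width,
                "n_max": config.motif_n_max}
               if config.motif_backend == "internal" else {}))
    adjacencies = [net.adjacency(expr.gene_ids) for net in networks]
    set_matrix = None
    if sets is not None:
        from .sets import set_membership_matrix
        set_matrix = set_membership_matrix(sets, expr.gene_ids)

    # fixed shuffled-sequence null reused by every motif scoring round
    null_onehots = None
    bg_freq = None
    if backend is not None and gene_seqs:
        null_onehots = _group_onehot(
            shuffled_null(gene_seqs, rng, config.motif_n_shuffles))
        bg_freq = background_frequencies(gene_seqs)

    S = ScoreMatrix(expr.gene_ids, np.zeros((expr.n_genes, k)), kind="S")
    have_motifs = False
    cluster_motifs: dict[int, list[MotifModel]] = {}
    records = []
    total = config.iterations

    for t in range(1, total + 1):
        state.iteration = t
        R = row_expression_scores(expr, state)
        matrices = [R.imputed()]
        weights = [config.scorer_entry("expression").weight]

        net_entry = config.scorer_entry("network")
        if networks and net_entry is not None and net_entry.active(t, total):
            T = network_scores(networks, state, adjacencies)
            matrices.append(T.values)
            weights.append(net_entry.weight)

        set_entry = config.scorer_entry("sets")
        if sets is not None and set_entry is not None and set_entry.active(t, total):
            E = set_enrichment_row_scores(sets, state, config.set_alpha,
                                          set_matrix=set_matrix)
            matrices.append(E.imputed())
            weights.append(set_entry.weight)

        motif_entry = config.scorer_entry("motif")
        if backend is not None and motif_entry is not None \
                and motif_entry.active(t, total):
            cluster_motifs = {}
            for j in range(k):
                roster_seqs = {g: gene_seqs[g] for g in state.gene_roster(j)
                               if g in gene_seqs}
                cluster_motifs[j] = backend.run(roster_seqs, config.motif_n_max)
            all_pvals = batch_score_clusters(cluster_motifs, gene_seqs, rng,
                                             config.motif_n_shuffles,
                                             null_onehots=null_onehots,
                                             bg_freq=bg_freq)
            for j in range(k):
                motif_row_scores(all_pvals[j], expr.gene_ids, S.values[:, j])
            have_motifs = True
        if have_motifs and motif_entry is not None:
            matrices.append(S.values)
            weights.append(motif_entry.weight * _motif_weight(
                t, total, config.motif_ramp_end))

        M = combine_scores(matrices, weights)
        M_noisy = anneal_noise(M, t, total, rng, config.noise_sd0)
        n_pick = max(1, int(round(config.sample_fraction * expr.n_genes)))
        rows = rng.choice(expr.n_genes, size=n_pick, replace=False)
        probs = kernel_membership_probs(M_noisy, state.cluster_sizes(),
                                        config.kernel_bandwidth_c,
                                        config.kernel_max_refs, rows=rows)
        n_moves = apply_moves(state, probs, "gene", rng,
                              min_size=config.min_cluster_genes,
                              max_size=config.max_cluster_genes, sampled=rows)

        Ccond = condition_scores(expr, state)
        Mc = anneal_noise(standard_cond(Ccond), t, total, rng, config.noise_sd0)
        n_cpick = max(1, int(round(config.sample_fraction * expr.n_conditions)))
        crows = rng.choice(expr.n_conditions, size=n_cpick, replace=False)
        cprobs = kernel_membership_probs(Mc, state.cond_membership.sum(axis=0),
                                         config.kernel_bandwidth_c,
                                         config.kernel_max_refs, rows=crows)
        apply_moves(state, cprobs, "condition", rng, min_size=2,
                    max_size=None, sampled=crows)

        if t == 1 or t == total or t % 10 == 0:
            records.append({
                "iteration": t,
                "noise_sd": float(
                    config.noise_sd0 * (total - t) / max(total - 1, 1)),
                "mean_residual": _mean_residual(expr, state),
                "mean_motif_pval": float(np.exp(S.values).mean())
                if have_motifs else np.nan,
                "mean_network_score": float(np.mean([m.mean() for m in
                                                     matrices[1:2]]))
                if len(matrices) > 1 and networks else np.nan,
                "n_gene_moves": n_moves,
            })
            if progress:
                r = records[-1]
                print(f"iter {t:5d}  resid {r['mean_residual']:.4f}  "
                      f"moves {n_moves}")

    stats = pd.DataFrame.from_records(records)
    return ResultsStore(config=config, state=state, stats=stats,
                        cluster_motifs=cluster_motifs)


def standard_cond(C: ScoreMatrix) -> np.ndarray:
    from .combine import standardize
    return standardize(C.imputed())


def _mean_residual(expr: ExpressionMatrix, state: MembershipState) -> float:
    vals = []
    for j in range(state.k):
        msr = mean_squared_residue(expr, state.gene_roster(j),
                                   state.condition_roster(j))
        if msr is not None:
            vals.append(msr)
    return float(np.mean(vals)) if vals else np.nan
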