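"""Synthetic desk-scale inputs with known ground truth.

The generator emulates the statistical structure the optimizer exploits:
modules of genes sharing a condition-restricted expression profile, a
common promoter motif implanted in most member promoters, denser network
connectivity inside modules, and gene sets mirroring module membership.
Every parameter is recorded in the output for provenance, and a fixed seed
reproduces the fixture byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (AssociationNetwork, ExpressionMatrix, GeneSetCollection,
                 PromoterSet)

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    n_genes: int = 400
    n_conditions: int = 60
    n_modules: int = 10
    genes_per_module: int = 20
    conditions_per_module: int = 20
    background_sd: float = 0.5
    signal_sd: float = 2.0            # sd of the shared module profile
    motif_width: int = 8
    implant_rate: float = 0.8
    motif_mutation_rate: float = 0.1
    promoter_length: int = 100
    intra_edge_prob: float = 0.3
    background_edge_prob: float = 0.02
    corrupt_sets: float = 0.0         # fraction of set members swapped out
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_module * self.n_modules > self.n_genes:
            raise ValueError("modules need more genes than the fixture has")
        if self.conditions_per_module > self.n_conditions:
            raise ValueError("module conditions exceed total conditions")


@dataclass
class GroundTruth:
    modules: list[dict] = field(default_factory=list)
    spec: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(motif: str, rng: np.random.Generator, rate: float) -> str:
    out = []
    for ch in motif:
        if rng.random() < rate:
            out.append(_BASES[int(rng.integers(0, 4))])
        else:
            out.append(ch)
    return "".join(out)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def make_fixture(spec: FixtureSpec | None = None):
    """Generate (expression, promoters, network, sets, regulons, truth)."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    conds = [f"c{i:03d}" for i in range(spec.n_conditions)]

    # disjoint gene modules over random condition subsets
    order = rng.permutation(spec.n_genes)
    truth = GroundTruth(spec=asdict(spec))
    module_genes: list[list[int]] = []
    module_conds: list[np.ndarray] = []
    motifs: list[str] = []
    for m in range(spec.n_modules):
        gi = order[m * spec.genes_per_module:(m + 1) * spec.genes_per_module]
        ci = rng.choice(spec.n_conditions, size=spec.conditions_per_module,
                        replace=False)
        motif = _random_seq(rng, spec.motif_width)
        module_genes.append(list(gi))
        module_conds.append(ci)
        motifs.append(motif)
        truth.modules.append({
            "module": m,
            "genes": [genes[i] for i in gi],
            "conditions": [conds[i] for i in ci],
            "motif": motif,
        })

    # expression: unit background noise, shared profile + noise inside modules
    X = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_conditions))
    for gi, ci in zip(module_genes, module_conds):
        profile = rng.normal(0.0, spec.signal_sd, size=len(ci))
        noise = rng.normal(0.0, spec.background_sd,
                           size=(len(gi), len(ci)))
        X[np.ix_(gi, ci)] = profile[None, :] + noise
    expr = ExpressionMatrix(genes, conds, X)

    # promoters: iid background with implanted (mutated) motif copies
    seqs: dict[str, str] = {g: _random_seq(rng, spec.promoter_length)
                            for g in genes}
    for gi, motif in zip(module_genes, motifs):
        for i in gi:
            if rng.random() >= spec.implant_rate:
                continue
            site = _mutate(motif, rng, spec.motif_mutation_rate)
            if rng.random() < 0.5:
                site = _revcomp(site)
            pos = int(rng.integers(0, spec.promoter_length - spec.motif_width))
            s = seqs[genes[i]]
            seqs[genes[i]] = s[:pos] + site + s[pos + spec.motif_width:]
    promoters = PromoterSet(seqs, "promoter")

    # network: Erdos-Renyi background, denser inside modules
    net = AssociationNetwork("fixture")
    n = spec.n_genes
    iu = np.triu_indices(n, k=1)
    base = rng.random(len(iu[0])) < spec.background_edge_prob
    in_module = np.zeros(n, dtype=int) - 1
    for m, gi in enumerate(module_genes):
        in_module[gi] = m
    same = (in_module[iu[0]] >= 0) & (in_module[iu[0]] == in_module[iu[1]])
    intra = same & (rng.random(len(iu[0])) < spec.intra_edge_prob)
    pick = base | intra
    weights = rng.uniform(0.5, 1.0, size=int(pick.sum()))
    for (a, b), w in zip(zip(iu[0][pick], iu[1][pick]), weights):
        net.add_edge(genes[a], genes[b], float(w))

    # gene sets mirror the modules (optionally corrupted)
    sets_dict: dict[str, set[str]] = {}
    for m, gi in enumerate(module_genes):
        members = {genes[i] for i in gi}
        if spec.corrupt_sets > 0:
            n_swap = int(round(spec.corrupt_sets * len(members)))
            if n_swap:
                drop = rng.choice(sorted(members), size=n_swap, replace=False)
                members -= set(drop)
                outside = [g for g in genes if in_module[genes.index(g)] != m]
                members |= set(rng.choice(outside, size=n_swap, replace=False))
        sets_dict[f"set{m:02d}"] = members
    collection = GeneSetCollection(sets_dict, genes)

    regulons = {f"TF{m:02d}": set(t["genes"]) for m, t in
                enumerate(truth.modules)}
    return expr, promoters, net, collection, regulons, truth


def score_recovery(clusters: list[set[str]], truth: GroundTruth,
                   jaccard_min: float = 0.5) -> float:
    """Fraction of true modules matched by some cluster at gene-Jaccard >=
    ``jaccard_min``."""
    if not truth.modules:
        return 0.0
    hits = 0
    for mod in truth.modules:
        target = set(mod["genes"])
        best = 0.0
        for cl in clusters:
            inter = len(cl & target)
            union = len(cl | target)
            if union:
                best = max(best, inter / union)
        if best >= jaccard_min:
            hits += 1
    return hits / len(truth.modules)
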