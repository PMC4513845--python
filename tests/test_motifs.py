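import numpy as np
import pytest

from comod.motifs import (BackendUnavailableError, InternalBackend, MemeBackend,
                          MotifModel, make_backend, motif_evaluation,
                          motif_row_scores, revcomp, score_sequences)


def _random_seqs(rng, n, length=80, prefix="g"):
    return {f"{prefix}{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            for i in range(n)}


def _implant(seqs, motif, rng, rate=1.0, genes=None):
    out = dict(seqs)
    for g in (genes or list(seqs)):
        if rng.random() >= rate:
            continue
        s = out[g]
        pos = int(rng.integers(0, len(s) - len(motif)))
        out[g] = s[:pos] + motif + s[pos + len(motif):]
    return out


MOTIF = "GTCATACG"


@pytest.fixture(scope="module")
def implanted_background():
    rng = np.random.default_rng(123)
    background = _random_seqs(rng, 60, 100)
    cluster_genes = [f"g{i}" for i in range(20)]
    implanted = _implant(background, MOTIF, rng, rate=0.75,
                         genes=cluster_genes[:15])
    return implanted, cluster_genes


class TestDetection:
    def test_implanted_kmer_recovered(self, implanted_background):
        seqs, cluster_genes = implanted_background
        backend = InternalBackend(seqs)
        models = backend.run({g: seqs[g] for g in cluster_genes})
        assert models, "no motif found despite implant"
        best = models[0]
        # consensus (possibly a sub-k-mer of the implant) must align to the
        # implanted site on either strand within Hamming distance 1
        w = len(best.consensus)
        hamming = min(
            sum(a != b for a, b in zip(best.consensus, target[off:off + w]))
            for target in (MOTIF, revcomp(MOTIF))
            for off in range(len(target) - w + 1))
        assert hamming <= 1
        assert best.evalue < 1e-3

    def test_result_capped_at_four(self, implanted_background):
        seqs, cluster_genes = implanted_background
        backend = InternalBackend(seqs)
        models = backend.run({g: seqs[g] for g in cluster_genes})
        assert len(models) <= 4
        # and ranked by significance
        evs = [m.evalue for m in models]
        assert evs == sorted(evs)

    def test_too_few_sequences_empty(self):
        rng = np.random.default_rng(0)
        seqs = _random_seqs(rng, 10)
        backend = InternalBackend(seqs)
        assert backend.run({g: seqs[g] for g in list(seqs)[:2]}) == []

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_random_sequences_yield_no_significant_motif(self, seed):
        rng = np.random.default_rng(seed)
        seqs = _random_seqs(rng, 80, 100)
        backend = InternalBackend(seqs)
        cluster = {g: seqs[g] for g in list(seqs)[:20]}
        models = backend.run(cluster)
        for m in models:
            assert m.pvalue > 0.05

    def test_strand_symmetry(self, implanted_background):
        seqs, cluster_genes = implanted_background
        rc_seqs = {g: revcomp(s) for g, s in seqs.items()}
        b1 = InternalBackend(seqs)
        b2 = InternalBackend(rc_seqs)
        m1 = b1.run({g: seqs[g] for g in cluster_genes})
        m2 = b2.run({g: rc_seqs[g] for g in cluster_genes})
        assert [m.evalue for m in m1] == pytest.approx(
            [m.evalue for m in m2], rel=1e-12)


class TestMotifModel:
    def test_pssm_rows_must_sum_to_one(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            MotifModel(pssm=bad, evalue=1.0, pvalue=1.0)

    def test_minimum_width(self):
        with pytest.raises(ValueError, match="width"):
            MotifModel(pssm=np.full((3, 4), 0.25), evalue=1.0, pvalue=1.0)


class TestScoring:
    def test_empty_motif_list_gives_all_ones(self):
        rng = np.random.default_rng(1)
        seqs = _random_seqs(rng, 5)
        assert score_sequences([], seqs) == {g: 1.0 for g in seqs}

    def test_consensus_carrier_beats_motif_free_gene(self, implanted_background):
        seqs, cluster_genes = implanted_background
        backend = InternalBackend(seqs)
        models = backend.run({g: seqs[g] for g in cluster_genes})
        rng = np.random.default_rng(2)
        probe = dict(seqs)
        probe["carrier"] = seqs["g40"][:40] + MOTIF + seqs["g40"][48:]
        pvals = score_sequences(models, probe, rng)
        motif_free = [pvals[f"g{i}"] for i in range(40, 60)]
        assert pvals["carrier"] < min(motif_free)

    def test_single_placement_matches_null_fraction_oracle(self):
        # sequence exactly as wide as the motif: one placement per strand;
        # p must equal the add-one-corrected fraction of null scores >= obs
        rng = np.random.default_rng(3)
        pssm = np.full((6, 4), 0.1)
        pssm[np.arange(6), [0, 1, 2, 3, 0, 1]] = 0.7
        model = MotifModel(pssm=pssm, evalue=0.5, pvalue=0.5)
        seqs = {"x": "ACGTAC", "y": "TTTTTT", "z": "GGGGGG"}
        n_shuffles = 500
        pvals = score_sequences([model], seqs,
                                np.random.default_rng(9), n_shuffles)
        # oracle: replay the same pooled null construction and exhaustive scan
        from comod.motifs import (_group_onehot, _logodds, _batch_best_scores,
                                  background_frequencies, shuffled_null,
                                  _onehot_names)
        bg = background_frequencies(seqs)
        lo = _logodds(model.pssm, bg)
        null = shuffled_null(seqs, np.random.default_rng(9), n_shuffles)

        def best(seq):
            def sc(s, mat):
                return sum(mat[i, "ACGT".index(ch)] for i, ch in enumerate(s))
            return max(sc(seq, lo), sc(revcomp(seq), lo))

        null_scores = np.array([best(s) for s in null.values()])
        for g, s in seqs.items():
            expected = (1 + (null_scores >= best(s) - 1e-12).sum()) / (
                1 + n_shuffles)
            assert pvals[g] == pytest.approx(expected, rel=1e-9)

    def test_gene_without_sequence_handled_by_caller_default(self):
        # motif_row_scores writes ln(p); missing genes default to p = 1 -> 0
        col = np.empty(3)
        motif_row_scores({"g1": 0.01, "g2": 1.0}, ["g1", "g2", "g3"], col)
        assert col[0] == pytest.approx(np.log(0.01))
        assert col[1] == 0.0
        assert col[2] == 0.0


class TestEvaluation:
    def test_no_motifs_fraction_zero(self):
        assert motif_evaluation({0: [], 1: []}, 2) == 0.0

    def test_fraction_bounds_and_counting(self):
        m_good = MotifModel(np.full((6, 4), 0.25), evalue=0.5, pvalue=0.5)
        m_bad = MotifModel(np.full((6, 4), 0.25), evalue=5.0, pvalue=1.0)
        frac = motif_evaluation({0: [m_good], 1: [m_bad], 2: []}, 3)
        assert frac == pytest.approx(1 / 3)
        assert 0.0 <= frac <= 1.0


def test_external_backend_probed_at_configuration_time(monkeypatch):
    monkeypatch.setattr("shutil.which", lambda name: None)
    with pytest.raises(BackendUnavailableError):
        MemeBackend()
    with pytest.raises(BackendUnavailableError):
        make_backend("weeder")


def test_make_backend_internal_requires_background():
    with pytest.raises(ValueError, match="background"):
        make_backend("internal")
    with pytest.raises(ValueError, match="unknown"):
        make_backend("nope")
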