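"""De-novo motif detection and per-gene sequence p-values.

Each cluster's member promoters (or 3'UTRs) are searched for over-represented
motifs; the top ``n <= 4`` motifs, ranked by significance, are turned into
PSSMs and every gene in the run is scored for the significance of its best
match (a sequence p-value).  The gene x cluster matrix S is the natural log
of those p-values, so lower is better and a motif-free gene scores 0.

Three backends satisfy the same contract:

* ``meme``   — external MEME for discovery, MAST for sequence p-values.
* ``weeder`` — external Weeder (medium mode, both strands) for discovery,
  MAST-style scanning of the returned PSSMs for p-values.
* ``internal`` — dependency-free k-mer enumeration: every canonical k-mer
  (k = 6..8, both strands collapsed) is tested for over-representation in
  the cluster versus the full sequence background with a hypergeometric
  tail, Bonferroni-corrected over all k-mers observable in the background.
  The best k-mers seed PSSMs built from their (mismatch-tolerant)
  occurrences.  Sequence p-values come from an empirical null of shuffled
  sequences.

External binaries are probed when the backend is constructed, never
mid-run.
"""

from __future__ import annotations

import shutil
import subprocess
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


class BackendUnavailableError(RuntimeError):
    """Raised at configuration time when an external binary is missing."""


@dataclass
class MotifModel:
    pssm: np.ndarray                   # width x 4 probabilities, rows sum to 1
    evalue: float                      # expected false discoveries at this score
    pvalue: float                      # min(1, evalue); valid p-value of the find
    sites: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 4:
            raise ValueError("PSSM must be width x 4")
        if self.pssm.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        rows = self.pssm.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("PSSM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.pssm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.pssm.argmax(axis=1))


# ---------------------------------------------------------------------------
# sequence encoding and k-mer machinery

def encode(seq: str) -> np.ndarray:
    """DNA -> int8 codes 0..3; ambiguity codes become -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_INDEX.get(ch, -1)
    return out


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp.get(ch, "N") for ch in reversed(seq.upper()))


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every valid k-window (4**k encoding), both handled later."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    valid = (win >= 0).all(axis=1)
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return (win[valid] * pows).sum(axis=1)


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = rc * 4 + (3 - (code % 4))
        code //= 4
    return rc


def _canonical(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-collapsed k-mer code: min(code, revcomp code)."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return np.minimum(codes, rc)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _presence_sets(sequences: dict[str, str], k: int) -> dict[str, set[int]]:
    return {g: set(_canonical(_kmer_codes(encode(s), k), k).tolist())
            for g, s in sequences.items()}


# ---------------------------------------------------------------------------
# internal backend

class InternalBackend:
    """K-mer over-representation motif finder with a fixed sequence background.

    ``background`` is the full promoter/UTR complement of the run; clusters
    hand in subsets of it.  Per width, the number of Bonferroni tests is the
    number of distinct canonical k-mers present anywhere in the background,
    which keeps the corrected p-value a valid (super-uniform) p-value for
    the best motif.
    """

    name = "internal"

    def __init__(self, background: dict[str, str], min_width: int = 6,
                 max_width: int = 8, n_max: int = 4, min_support: int = 2):
        self.background = dict(background)
        self.widths = list(range(min_width, max_width + 1))
        self.n_max = n_max
        self.min_support = min_support
        self._bg_presence = {k: _presence_sets(self.background, k)
                             for k in self.widths}
        self._bg_counts = {k: Counter(code for s in self._bg_presence[k].values()
                                      for code in s)
                           for k in self.widths}
        self.n_tests = sum(len(self._bg_counts[k]) for k in self.widths)

    def run(self, sequences: dict[str, str],
            n_max: int | None = None) -> list[MotifModel]:
        """Detect up to ``n_max`` motifs in a cluster's sequences."""
        n_max = self.n_max if n_max is None else min(n_max, self.n_max)
        if len(sequences) < 3:
            return []
        n_cluster = len(sequences)
        n_bg = len(self.background)
        candidates: list[tuple[float, int, int, int]] = []  # (p, width, code, count)
        for k in self.widths:
            cluster_counts: Counter = Counter()
            for gene in sequences:
                pres = self._bg_presence[k].get(gene)
                if pres is None:
                    pres = set(_canonical(_kmer_codes(encode(sequences[gene]), k),
                                          k).tolist())
                cluster_counts.update(pres)
            codes = [c for c, cnt in cluster_counts.items()
                     if cnt >= self.min_support]
            if not codes:
                continue
            counts = np.array([cluster_counts[c] for c in codes])
            K = np.array([self._bg_counts[k].get(c, cluster_counts[c])
                          for c in codes])
            pv = hypergeom.sf(counts - 1, n_bg, K, n_cluster)
            for c, cnt, p in zip(codes, counts, pv):
                candidates.append((float(p), k, int(c), int(cnt)))
        candidates.sort()
        chosen: list[tuple[float, int, int, int]] = []
        for cand in candidates:
            if len(chosen) >= n_max:
                break
            if any(self._similar(cand, prev) for prev in chosen):
                continue
            chosen.append(cand)
        models = []
        for p, k, code, _ in chosen:
            model = self._build_pssm(sequences, k, code, p)
            if model is not None:
                models.append(model)
        return models

    @staticmethod
    def _similar(a: tuple, b: tuple) -> bool:
        """Same-width k-mers within Hamming distance 1 (either strand)."""
        _, ka, ca, _ = a
        _, kb, cb, _ = b
        if ka != kb:
            return False
        for other in (cb, _rc_code(cb, kb)):
            x, y, diff = ca, other, 0
            for _ in range(ka):
                if x % 4 != y % 4:
                    diff += 1
                x //= 4
                y //= 4
            if diff <= 1:
                return True
        return False

    def _build_pssm(self, sequences: dict[str, str], k: int, code: int,
                    p: float) -> MotifModel | None:
        """Align occurrences of the seed k-mer (Hamming <= 1, both strands)."""
        seed = _decode(code, k)
        target = encode(seed)
        target_rc = encode(revcomp(seed))
        counts = np.full((k, 4), 0.5)  # pseudocount
        sites: list[tuple[str, int, str]] = []
        for gene, seq in sequences.items():
            codes = encode(seq)
            if len(codes) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            ok = (win >= 0).all(axis=1)
            for strand, tgt in (("+", target), ("-", target_rc)):
                hits = np.flatnonzero(ok & ((win != tgt).sum(axis=1) <= 1))
                for pos in hits:
                    w = win[pos] if strand == "+" else (3 - win[pos])[::-1]
                    counts[np.arange(k), w] += 1.0
                    sites.append((gene, int(pos), strand))
        if not sites:
            return None
        pssm = counts / counts.sum(axis=1, keepdims=True)
        evalue = p * self.n_tests
        return MotifModel(pssm=pssm, evalue=evalue,
                          pvalue=min(1.0, evalue), sites=sites)


# ---------------------------------------------------------------------------
# external backends (thin subprocess wrappers; probed at construction)

class MemeBackend:
    """MEME for discovery (zoops, both strands), MAST for sequence p-values."""

    name = "meme"

    def __init__(self, min_width: int = 6, max_width: int = 24,
                 n_max: int = 4, workdir: str | Path = "."):
        for binary in ("meme", "mast"):
            if shutil.which(binary) is None:
                raise BackendUnavailableError(
                    f"{binary!r} not found on PATH; install the MEME suite or "
                    f"use motif_backend=internal")
        self.min_width = min_width
        self.max_width = max_width
        self.n_max = n_max
        self.workdir = Path(workdir)

    def run(self, sequences: dict[str, str],
            n_max: int | None = None) -> list[MotifModel]:
        n_max = self.n_max if n_max is None else min(n_max, self.n_max)
        if len(sequences) < 3:
            return []
        self.workdir.mkdir(parents=True, exist_ok=True)
        fasta = self.workdir / "cluster.fasta"
        with open(fasta, "w") as fh:
            for gene, seq in sequences.items():
                fh.write(f">{gene}\n{seq}\n")
        out = self.workdir / "meme_out"
        cmd = ["meme", str(fasta), "-dna", "-revcomp", "-mod", "zoops",
               "-nmotifs", str(n_max), "-minw", str(self.min_width),
               "-maxw", str(self.max_width), "-text"]
        res = subprocess.run(cmd, capture_output=True, text=True, check=True,
                             cwd=str(out.parent))
        return parse_meme_text(res.stdout)[:n_max]


class WeederBackend:
    """Weeder in medium mode on both strands; PSSMs parsed from its output."""

    name = "weeder"

    def __init__(self, n_max: int = 4, organism: str = "HS",
                 workdir: str | Path = "."):
        if shutil.which("weederlauncher") is None and shutil.which("weeder2") is None:
            raise BackendUnavailableError(
                "no Weeder launcher found on PATH; use motif_backend=internal")
        self.n_max = n_max
        self.organism = organism
        self.workdir = Path(workdir)

    def run(self, sequences: dict[str, str],
            n_max: int | None = None) -> list[MotifModel]:
        n_max = self.n_max if n_max is None else min(n_max, self.n_max)
        if len(sequences) < 3:
            return []
        self.workdir.mkdir(parents=True, exist_ok=True)
        fasta = self.workdir / "cluster.fasta"
        with open(fasta, "w") as fh:
            for gene, seq in sequences.items():
                fh.write(f">{gene}\n{seq}\n")
        if shutil.which("weeder2"):
            cmd = ["weeder2", "-f", str(fasta), "-O", self.organism, "-b", str(n_max)]
        else:
            cmd = ["weederlauncher", str(fasta), self.organism, "medium", "S"]
        subprocess.run(cmd, capture_output=True, text=True, check=True)
        matrix_file = Path(str(fasta) + ".matrix.w2")
        if not matrix_file.exists():
            return []
        return parse_weeder_matrices(matrix_file.read_text())[:n_max]


def parse_meme_text(text: str) -> list[MotifModel]:
    """Extract PSSMs and E-values from MEME's text output."""
    models: list[MotifModel] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if "position-specific probability matrix" in line.lower():
            evalue = 1.0
            j = i
            while j >= 0 and "E-value" not in lines[j]:
                j -= 1
            if j >= 0:
                try:
                    evalue = float(lines[j].split("E-value =")[-1].split()[0])
                except (ValueError, IndexError):
                    pass
            rows = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                        i += 1
                        continue
                    except ValueError:
                        pass
                if rows:
                    break
                i += 1
            if len(rows) >= 4:
                pssm = np.asarray(rows)
                pssm = pssm / pssm.sum(axis=1, keepdims=True)
                models.append(MotifModel(pssm=pssm, evalue=evalue,
                                         pvalue=min(1.0, evalue)))
        i += 1
    models.sort(key=lambda m: m.evalue)
    return models


def parse_weeder_matrices(text: str) -> list[MotifModel]:
    """Parse Weeder2 .matrix.w2 frequency matrices into MotifModels."""
    models: list[MotifModel] = []
    rows: list[list[float]] = []
    score = 0.0

    def flush():
        nonlocal rows, score
        if len(rows) >= 4:
            pssm = np.asarray(rows) + 0.25
            pssm = pssm / pssm.sum(axis=1, keepdims=True)
            ev = 10.0 ** (-score) if score > 0 else 1.0
            models.append(MotifModel(pssm=pssm, evalue=ev, pvalue=min(1.0, ev)))
        rows, score = [], 0.0

    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith(">"):
            flush()
            parts = line.split()
            if len(parts) > 2:
                try:
                    score = float(parts[-1])
                except ValueError:
                    score = 0.0
            continue
        parts = line.split()
        if len(parts) == 5:
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                pass
    flush()
    models.sort(key=lambda m: m.evalue)
    return models


def make_backend(name: str, background: dict[str, str] | None = None,
                 **kwargs):
    if name == "internal":
        if background is None:
            raise ValueError("internal backend needs background sequences")
        return InternalBackend(background, **kwargs)
    if name == "meme":
        return MemeBackend(**kwargs)
    if name == "weeder":
        return WeederBackend(**kwargs)
    raise ValueError(f"unknown motif backend {name!r}")


# ---------------------------------------------------------------------------
# sequence p-values and the S matrix

def _logodds(pssm: np.ndarray, bg: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(pssm, 1e-9)) - np.log(np.maximum(bg, 1e-9))


def _batch_best_scores(logodds_list: list[np.ndarray],
                       onehots: dict[int, tuple[list[str], np.ndarray]],
                       _cache: dict | None = None) -> np.ndarray:
    """Best log-odds hit per (sequence, motif) over both strands.

    ``onehots`` groups sequences by length: length -> (names, n x L x 4).
    Returns an array aligned with the concatenation of the group name lists
    (use :func:`_onehot_names` for the row order).  Motifs are grouped by
    width so each group costs one GEMM against the precomputed windows;
    ``_cache`` (keyed by (id(group), width)) lets callers reuse windows
    across calls within one scoring round.
    """
    n_seq = sum(len(names) for names, _ in onehots.values())
    out = np.full((n_seq, len(logodds_list)), -np.inf)
    by_width: dict[int, list[int]] = {}
    for idx, lo in enumerate(logodds_list):
        by_width.setdefault(lo.shape[0], []).append(idx)
    for w, idxs in by_width.items():
        # stack forward and reverse-complement orientations
        stack = np.stack([logodds_list[i].reshape(-1) for i in idxs] +
                         [logodds_list[i][::-1, ::-1].reshape(-1)
                          for i in idxs], axis=1)          # 4w x 2m
        row = 0
        for length, (names, oh) in onehots.items():
            n = len(names)
            if length < w:
                row += n
                continue
            key = (id(oh), w)
            win = _cache.get(key) if _cache is not None else None
            if win is None:
                win = np.lib.stride_tricks.sliding_window_view(
                    oh, (w, 4), axis=(1, 2)).reshape(n * (length - w + 1), w * 4)
                if _cache is not None:
                    _cache[key] = win
            scores = (win @ stack).reshape(n, length - w + 1, 2 * len(idxs))
            best = scores.max(axis=1)                      # n x 2m
            m = len(idxs)
            both = np.maximum(best[:, :m], best[:, m:])
            out[row:row + n, idxs] = both
            row += n
    return out


def _onehot_names(onehots: dict[int, tuple[list[str], np.ndarray]]) -> list[str]:
    return [name for names, _ in onehots.values() for name in names]


def _group_onehot(sequences: dict[str, str]) -> dict[int, tuple[list[str], np.ndarray]]:
    groups: dict[int, list[str]] = {}
    for name, seq in sequences.items():
        groups.setdefault(len(seq), []).append(name)
    out: dict[int, tuple[list[str], np.ndarray]] = {}
    for length, names in groups.items():
        oh = np.zeros((len(names), length, 4))
        for i, name in enumerate(names):
            codes = encode(sequences[name])
            valid = codes >= 0
            oh[i, np.flatnonzero(valid), codes[valid]] = 1.0
        out[length] = (names, oh)
    return out


def shuffled_null(sequences: dict[str, str], rng: np.random.Generator,
                  n_shuffles: int = 1000) -> dict[str, str]:
    """Pooled null: letter-shuffled copies of the input sequences."""
    names = list(sequences)
    null: dict[str, str] = {}
    for i in range(n_shuffles):
        src = sequences[names[i % len(names)]]
        letters = list(src)
        rng.shuffle(letters)
        null[f"null_{i}"] = "".join(letters)
    return null


def background_frequencies(sequences: dict[str, str]) -> np.ndarray:
    counts = np.full(4, 1.0)
    for seq in sequences.values():
        codes = encode(seq)
        for b in range(4):
            counts[b] += (codes == b).sum()
    return counts / counts.sum()


def batch_score_clusters(cluster_motifs: dict[int, list[MotifModel]],
                         sequences: dict[str, str],
                         rng: np.random.Generator | None = None,
                         n_shuffles: int = 1000,
                         null_onehots=None,
                         bg_freq: np.ndarray | None = None
                         ) -> dict[int, dict[str, float]]:
    """Sequence p-values for every cluster's motif set in one pass.

    Per motif, p is the fraction of shuffled-sequence null scores at least
    as large as the gene's best hit (add-one corrected); within a cluster
    the per-gene minimum over its motifs is Sidak-combined.  Genes without
    a sequence get 1.0.  All motifs of all clusters are scored together so
    the sliding-window tensors are built once per width.
    """
    if bg_freq is None:
        bg_freq = background_frequencies(sequences)
    onehots = _group_onehot(sequences)
    if null_onehots is None:
        rng = np.random.default_rng(0) if rng is None else rng
        null_onehots = _group_onehot(shuffled_null(sequences, rng, n_shuffles))
    flat: list[np.ndarray] = []
    span: dict[int, tuple[int, int]] = {}
    for j, models in cluster_motifs.items():
        start = len(flat)
        flat.extend(_logodds(m.pssm, bg_freq) for m in models)
        span[j] = (start, len(flat))
    out: dict[int, dict[str, float]] = {j: {g: 1.0 for g in sequences}
                                        for j in cluster_motifs}
    if not flat:
        return out
    cache: dict = {}
    obs = _batch_best_scores(flat, onehots, cache)          # n_seq x n_motifs
    null = _batch_best_scores(flat, null_onehots, cache)    # n_null x n_motifs
    null.sort(axis=0)
    n_null = null.shape[0]
    names = _onehot_names(onehots)
    # p per (gene, motif): add-one-corrected rank in the null
    P = np.empty_like(obs)
    for c in range(obs.shape[1]):
        ge = n_null - np.searchsorted(null[:, c], obs[:, c], side="left")
        P[:, c] = (1.0 + ge) / (1.0 + n_null)
    for j, (a, b) in span.items():
        if a == b:
            continue
        m = b - a
        pmin = P[:, a:b].min(axis=1)
        comb = 1.0 - (1.0 - pmin) ** m if m > 1 else pmin
        comb = np.clip(comb, 1e-300, 1.0)
        out[j] = dict(zip(names, comb.tolist()))
    return out


def score_sequences(motifs: list[MotifModel], sequences: dict[str, str],
                    rng: np.random.Generator | None = None,
                    n_shuffles: int = 1000,
                    null_onehots=None, bg_freq: np.ndarray | None = None
                    ) -> dict[str, float]:
    """Sequence p-value of each gene's best combined match to ``motifs``."""
    if not motifs:
        return {g: 1.0 for g in sequences}
    return batch_score_clusters({0: motifs}, sequences, rng, n_shuffles,
                                null_onehots, bg_freq)[0]


def motif_row_scores(p_values: dict[str, float], gene_ids: list[str],
                     column: np.ndarray) -> None:
    """Fill one cluster's column of S with ln(sequence p-value) in place."""
    for i, gene in enumerate(gene_ids):
        p = p_values.get(gene, 1.0)
        column[i] = np.log(p)


def motif_evaluation(cluster_motifs: dict[int, list[MotifModel]],
                     n_clusters: int, threshold: float = 1.0) -> float:
    """Fraction of clusters whose best motif significance is <= threshold."""
    if n_clusters == 0:
        return 0.0
    hits = 0
    for models in cluster_motifs.values():
        if models and min(m.evalue for m in models) <= threshold:
            hits += 1
    return hits / n_clusters
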