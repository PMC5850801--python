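"""Felsenstein pruning likelihood for nucleotide alignments on gene trees.

Substitution models are reversible CTMCs (JC, HKY, GTR) whose rate matrix is
normalized to one expected substitution per unit of rate x time, so branch
rates and durations enter the likelihood only through their product.
Among-site rate variation uses the discrete-gamma approximation: equal-weight
categories whose rates are the within-bin means (mean 1 overall), and the
site likelihood averages the pruning result over categories.

Ambiguity codes (IUPAC) and gaps become partial-state tip vectors with a 1
for every compatible base, which is also how unphased heterozygous sites are
represented downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO
from scipy.stats import gamma as gamma_dist

from .trees import GeneTree

__all__ = [
    "SubstModel",
    "SiteRateModel",
    "Alignment",
    "transition_probabilities",
    "locus_log_likelihood",
    "site_pattern_compress",
    "IUPAC_PARTIALS",
    "jukes_cantor",
    "hky",
]

_BASES = "ACGT"

IUPAC_PARTIALS: dict[str, tuple[float, float, float, float]] = {}
for _code, _bases in {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT",
}.items():
    IUPAC_PARTIALS[_code] = tuple(1.0 if b in _bases else 0.0 for b in _BASES)

# reverse lookup for collapsing two bases into one ambiguity code
PAIR_TO_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


class SubstModel:
    """Reversible nucleotide substitution model with cached eigensystem."""

    def __init__(self, kind: str = "JC", kappa: float = 1.0,
                 exchangeabilities: np.ndarray | None = None,
                 freqs: np.ndarray | None = None):
        self.kind = kind
        self.kappa = float(kappa)
        if freqs is None:
            freqs = np.full(4, 0.25)
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
            raise ValueError("frequencies must be 4 positive values summing to 1")
        self.freqs = freqs / freqs.sum()
        if kind == "JC":
            ex = np.ones(6)
            self.freqs = np.full(4, 0.25)
        elif kind == "HKY":
            # order: AC, AG, AT, CG, CT, GT; transitions AG and CT
            ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        elif kind == "GTR":
            if exchangeabilities is None:
                raise ValueError("GTR requires 6 exchangeabilities")
            ex = np.asarray(exchangeabilities, dtype=float)
            if ex.shape != (6,) or (ex <= 0).any():
                raise ValueError("need 6 positive exchangeabilities")
        else:
            raise ValueError(f"unknown substitution model {kind!r}")
        self.exchangeabilities = ex
        self._build()

    def _build(self) -> None:
        pi = self.freqs
        R = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        R[iu] = self.exchangeabilities
        R = R + R.T
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to 1 expected substitution per unit distance
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        s = np.sqrt(pi)
        B = (Q * s[:, None]) / s[None, :]
        B = 0.5 * (B + B.T)  # symmetric up to round-off
        w, V = np.linalg.eigh(B)
        self._eval = w
        self._left = V.T * s[None, :]          # V^T diag(sqrt pi)
        self._right = (1.0 / s)[:, None] * V   # diag(1/sqrt pi) V

    def transition(self, distance: float | np.ndarray) -> np.ndarray:
        """P(d) for scalar d -> (4,4), or batch of d -> (k,4,4)."""
        d = np.asarray(distance, dtype=float)
        if (d < 0).any():
            raise ValueError("distance must be non-negative")
        expwd = np.exp(np.multiply.outer(d, self._eval))  # (..., 4)
        P = np.einsum("ij,...j,jk->...ik", self._right, expwd, self._left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P


def jukes_cantor() -> SubstModel:
    return SubstModel("JC")


def hky(kappa: float, freqs: np.ndarray | None = None) -> SubstModel:
    return SubstModel("HKY", kappa=kappa, freqs=freqs)


def transition_probabilities(model: SubstModel, distance: float) -> np.ndarray:
    """4x4 stochastic transition matrix over a branch of the given
    expected-substitutions distance."""
    return model.transition(float(distance))


@dataclass(frozen=True)
class SiteRateModel:
    """Discrete-gamma among-site rate variation (equal-weight categories).

    Category rates are the analytical means of the gamma quantile bins,
    renormalized to mean exactly 1.  ``n_categories = 1`` means no rate
    variation.
    """

    n_categories: int = 4
    alpha: float = 1.0

    def rates(self) -> np.ndarray:
        k, a = self.n_categories, self.alpha
        if k < 1:
            raise ValueError("need at least one rate category")
        if k == 1:
            return np.ones(1)
        if a <= 0:
            raise ValueError("gamma shape must be positive")
        # X ~ Gamma(a, scale=1/a); E[X | bin] via the shape a+1 identity
        edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a, scale=1.0 / a)
        upper = gamma_dist.cdf(edges[1:], a + 1.0, scale=1.0 / a)
        lower = gamma_dist.cdf(edges[:-1], a + 1.0, scale=1.0 / a)
        rates = (upper - lower) * k
        return rates / rates.mean()


class Alignment:
    """Rectangular multiple sequence alignment over unique taxa."""

    def __init__(self, taxa: list[str], sequences: list[str]):
        if len(taxa) != len(sequences):
            raise ValueError("one sequence per taxon required")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError("alignment is not rectangular")
        self.taxa = list(taxa)
        self.sequences = [s.upper() for s in sequences]
        for s in self.sequences:
            bad = set(s) - set(IUPAC_PARTIALS)
            if bad:
                raise ValueError(f"unknown residue codes: {sorted(bad)}")
        self._patterns = None
        self._tip_partials: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    @classmethod
    def read(cls, path, schema: str = "fasta") -> "Alignment":
        """Read FASTA or NEXUS (DATA/CHARACTERS blocks, interleaved or not)."""
        aln = AlignIO.read(str(path), schema)
        return cls([rec.id for rec in aln], [str(rec.seq) for rec in aln])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        if self._patterns is None:
            self._patterns = site_pattern_compress(self)
        return self._patterns

    def tip_partials(self, taxon: str) -> np.ndarray:
        """(n_patterns, 4) partial-likelihood matrix for one taxon (cached)."""
        if taxon not in self._tip_partials:
            cols, _ = self.patterns()
            row = cols[self.taxa.index(taxon)]
            self._tip_partials[taxon] = np.array(
                [IUPAC_PARTIALS[c] for c in row])
        return self._tip_partials[taxon]


def site_pattern_compress(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their multiplicities.

    Returns (columns, weights) where ``columns[i, j]`` is taxon i's residue
    in unique pattern j; the likelihood over compressed patterns weighted by
    multiplicity equals the uncompressed likelihood.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(s) for s in alignment.sequences])
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


def locus_log_likelihood(alignment: Alignment, gene_tree: GeneTree,
                         branch_rates: dict[int, float], model: SubstModel,
                         site_rates: SiteRateModel | None = None) -> float:
    """Pruning log-likelihood of one locus.

    ``branch_rates`` maps the node below each branch to its clock rate; the
    per-branch distance is rate x duration, scaled by each gamma category
    rate, and site likelihoods average equally over categories.  Per-pattern
    rescaling guards against underflow.
    """
    tree_tips = set(gene_tree.tip_labels())
    if tree_tips != set(alignment.taxa):
        raise ValueError("alignment taxa do not match gene tree tips")
    cat_rates = site_rates.rates() if site_rates is not None else np.ones(1)
    ncat = len(cat_rates)
    _, weights = alignment.patterns()
    npat = len(weights)

    # batch all branch transition matrices in one eigen-decomposed call
    order = list(gene_tree.postorder())
    branch_nodes = [n for n in order if n.parent is not None]
    dists = np.empty((len(branch_nodes), ncat))
    for i, n in enumerate(branch_nodes):
        rate = branch_rates[n.id]
        if rate <= 0:
            raise ValueError("branch rates must be positive")
        dists[i] = rate * (n.parent.height - n.height) * cat_rates
    P_all = model.transition(dists)  # (nbranch, ncat, 4, 4)
    P_of = {n.id: P_all[i] for i, n in enumerate(branch_nodes)}

    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(npat)
    for node in order:
        if node.is_tip():
            tipp = alignment.tip_partials(node.label)  # (npat, 4)
            partials[node.id] = np.broadcast_to(tipp, (ncat, npat, 4))
            continue
        acc = None
        for ch in node.children:
            down = np.einsum("kij,kpj->kpi", P_of[ch.id], partials[ch.id])
            acc = down if acc is None else acc * down
            del partials[ch.id]
        m = acc.max(axis=(0, 2))  # per-pattern scale
        m[m <= 0] = 1.0
        acc /= m[None, :, None]
        log_scale += np.log(m)
        partials[node.id] = acc

    root = partials[gene_tree.root.id]  # (ncat, npat, 4)
    site_lik = np.einsum("kpj,j->p", root, model.freqs) / ncat
    if (site_lik <= 0).any():
        return -math.inf
    return float(np.dot(weights, np.log(site_lik) + log_scale))
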