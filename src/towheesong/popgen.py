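"""Sequence-based population differentiation.

Aligned-FASTA I/O, SNP extraction, pairwise sequence distances, and PhiST
via a two-level AMOVA on squared pairwise distances.  The model is haploid
(mtDNA) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with population labels."""

    ids: list[str]
    sequences: list[str]
    labels: list[str]
    coords: list[tuple[float, float]] | None = None  # (lat, lon) per sequence

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise ValueError("ids, sequences, and labels must pair up")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            ragged = [i for i, s in zip(self.ids, self.sequences) if len(s) != len(self.sequences[0])]
            raise ValueError(f"ragged alignment; offending ids: {ragged}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def char_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


@dataclass
class AmovaResult:
    """Two-level AMOVA variance components and PhiST."""

    sigma_among: float
    sigma_within: float
    phi_st: float
    pct_between: float
    pct_within: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    n0: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sigma_among": self.sigma_among,
            "sigma_within": self.sigma_within,
            "phi_st": self.phi_st,
            "pct_between": self.pct_between,
            "pct_within": self.pct_within,
            "flags": self.flags,
        }


def read_alignment(path: str | Path, labels_path: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA.

    Population labels come from a sidecar CSV (columns: id, population, and
    optionally lat, lon) when given; otherwise from an ``id|population``
    header convention.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or unreadable FASTA: {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    coords = None
    if labels_path is not None:
        table = pd.read_csv(labels_path).set_index("id")
        missing = [i for i in ids if i not in table.index]
        if missing:
            raise ValueError(f"ids missing from label table: {missing}")
        labels = [str(table.loc[i, "population"]) for i in ids]
        if {"lat", "lon"} <= set(table.columns):
            coords = [(float(table.loc[i, "lat"]), float(table.loc[i, "lon"])) for i in ids]
    else:
        labels = []
        for i in ids:
            if "|" not in i:
                raise ValueError(f"no label table and id lacks '|population' suffix: {i}")
            labels.append(i.rsplit("|", 1)[1])
    return Alignment(ids, seqs, labels, coords)


def write_alignment(aln: Alignment, fasta_path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write aligned FASTA (and optional label/coordinate sidecar CSV)."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if labels_path is not None:
        rows = {"id": aln.ids, "population": aln.labels}
        if aln.coords is not None:
            rows["lat"] = [c[0] for c in aln.coords]
            rows["lon"] = [c[1] for c in aln.coords]
        pd.DataFrame(rows).to_csv(labels_path, index=False)


def snp_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Sample x site matrix of variant genotypes at polymorphic sites.

    Major allele is coded 0, any minor allele 1 (haploid); gaps and IUPAC
    ambiguity codes are missing (NaN).  Returns (matrix, site positions).
    """
    chars = aln.char_matrix()
    n, L = chars.shape
    cols = []
    positions = []
    for j in range(L):
        col = chars[:, j]
        valid = np.isin(col, list(_VALID_BASES))
        alleles, counts = np.unique(col[valid], return_counts=True)
        if len(alleles) < 2:
            continue
        # Deterministic major allele: max count, alphabetical tie-break.
        major = alleles[np.lexsort((alleles, -counts))][0]
        enc = np.full(n, np.nan)
        enc[valid] = (col[valid] != major).astype(float)
        cols.append(enc)
        positions.append(j)
    if not cols:
        warnings.warn("no polymorphic sites in alignment")
        return np.empty((n, 0)), np.array([], dtype=int)
    return np.column_stack(cols), np.array(positions, dtype=int)


def seq_distance_matrix(aln: Alignment, mode: str = "sqrt_mismatch") -> np.ndarray:
    """Pairwise distances over shared ungapped sites.

    ``sqrt_mismatch`` (default) reports the square root of the mismatch
    proportion; ``p_distance`` reports the raw proportion.
    """
    if mode not in {"sqrt_mismatch", "p_distance"}:
        raise ValueError(f"unknown mode: {mode}")
    chars = aln.char_matrix()
    valid = np.isin(chars, list(_VALID_BASES))
    n = len(chars)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        shared = valid[i] & valid[j]
        n_shared = int(shared.sum())
        if n_shared == 0:
            raise ValueError(f"no shared ungapped sites between {aln.ids[i]} and {aln.ids[j]}")
        p = float(np.mean(chars[i, shared] != chars[j, shared]))
        d = np.sqrt(p) if mode == "sqrt_mismatch" else p
        out[i, j] = out[j, i] = d
    return out


def amova_two_level(
    data: Alignment | np.ndarray,
    labels: list[str] | np.ndarray | None = None,
) -> AmovaResult:
    """Two-level AMOVA from squared pairwise distances.

    Accepts either an :class:`Alignment` (pairwise-difference distances are
    computed internally) or a precomputed distance matrix plus labels.
    Unequal sample sizes are handled with the standard n0 coefficient.
    Negative among-population components are reported raw but floored at 0
    for the percentage split.
    """
    if isinstance(data, Alignment):
        dist = seq_distance_matrix(data, mode="p_distance") * data.length
        labels = np.asarray(data.labels)
    else:
        dist = np.asarray(data, dtype=float)
        if labels is None:
            raise ValueError("labels required with a distance matrix")
        labels = np.asarray(labels)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    pops, inverse = np.unique(labels, return_inverse=True)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    flags = []
    sizes = np.bincount(inverse)
    if (sizes == 1).any():
        flags.append("population with a single sequence: within-component is weakly determined")

    d2 = dist**2
    # SS_total = sum over all unordered pairs of d^2 / N
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for k in range(len(pops)):
        idx = np.flatnonzero(inverse == k)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = len(pops) - 1
    df_within = n - len(pops)
    if df_within == 0:
        raise ValueError("every population has a single sequence; AMOVA undefined")
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    sigma_among_f = max(sigma_among, 0.0)
    total = sigma_among_f + sigma_within
    if total <= 0:
        phi = 0.0
        pct_between, pct_within = 0.0, 100.0
        flags.append("zero total variance")
    else:
        phi = sigma_among / (sigma_among + sigma_within)
        pct_between = 100.0 * sigma_among_f / total
        pct_within = 100.0 * sigma_within / total
    return AmovaResult(
        sigma_among=float(sigma_among),
        sigma_within=float(sigma_within),
        phi_st=float(phi),
        pct_between=float(pct_between),
        pct_within=float(pct_within),
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        df_among=int(df_among),
        df_within=int(df_within),
        n0=float(n0),
        flags=flags,
    )


def pairwise_phi_st(aln: Alignment, labels: list[str] | None = None) -> pd.DataFrame:
    """PhiST (via two-level AMOVA) for each pair of populations."""
    labels = np.asarray(labels if labels is not None else aln.labels)
    dist = seq_distance_matrix(aln, mode="p_distance") * aln.length
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rows = []
    for a, b in combinations(pops, 2):
        idx = np.flatnonzero(np.isin(labels, [a, b]))
        res = amova_two_level(dist[np.ix_(idx, idx)], labels[idx])
        rows.append({"pop_a": a, "pop_b": b, "phi_st": res.phi_st,
                     "pct_between": res.pct_between, "pct_within": res.pct_within})
    return pd.DataFrame(rows)


def phi_st_permutation_test(
    data: Alignment | np.ndarray,
    labels: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for PhiST by shuffling population labels.

    Returns (observed PhiST, one-sided upper-tail p with the +1 correction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(data, Alignment):
        dist = seq_distance_matrix(data, mode="p_distance") * data.length
        labels = np.asarray(data.labels)
    else:
        dist = np.asarray(data, dtype=float)
        labels = np.asarray(labels)
    obs = amova_two_level(dist, labels).phi_st
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if amova_two_level(dist, perm).phi_st >= obs:
            count += 1
    return obs, (1 + count) / (n_perm + 1)
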