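"""Mutational-signature extraction by KL-divergence NMF.

The spectrum (contexts x samples) is factorized as V ~ W H with
multiplicative updates minimizing the generalized Kullback-Leibler
divergence, the standard objective in mutational-signature work.
Several random restarts are run and the best final objective kept;
W columns are normalized to probability vectors with the scale
absorbed into the exposures H. Extracted signatures are matched to a
reference catalog by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consequence import CONTEXT_CLASSES, SpectrumMatrix

_EPS = 1e-12


@dataclass
class SignatureSet:
    """Fitted factorization: W (96 x k, columns sum to 1), H (k x samples)."""

    W: pd.DataFrame  # index: context classes, columns: signature names
    H: pd.DataFrame  # index: signature names, columns: sample ids
    k: int
    objective_trace: np.ndarray  # per-iteration generalized KL of the best restart

    @property
    def signature_names(self) -> list[str]:
        return list(self.W.columns)


def _gkl(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask]) - V[mask]) + WH.sum()
    return float(div)


def _nmf_single(V: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = V.shape
    scale = np.sqrt(V.mean() / k) + _EPS
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = _gkl(V, W @ H)
        trace.append(obj)
        if prev < np.inf and prev - obj <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return W, H, trace


def nmf_extract(
    spectrum: SpectrumMatrix | pd.DataFrame,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> SignatureSet:
    """Best-of-restarts KL-NMF of a samples x 96 spectrum.

    Deterministic given ``seed``; ties between restarts go to the
    lowest restart index. Raises on an all-zero spectrum or a rank
    outside ``1 <= k <= min(96, n_samples)``.
    """
    counts = spectrum.counts if isinstance(spectrum, SpectrumMatrix) else spectrum
    V = counts.to_numpy(dtype=float).T  # contexts x samples
    if V.sum() <= 0:
        raise ValueError("spectrum is all zero; nothing to factorize")
    if not (1 <= k <= min(V.shape)):
        raise ValueError(f"k={k} outside 1..min(96, n_samples)={min(V.shape)}")
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for idx, ss in enumerate(seeds):
        W, H, trace = _nmf_single(V, k, np.random.default_rng(ss), max_iter, tol)
        if best is None or trace[-1] < best[3][-1]:  # strict <: ties keep lowest index
            best = (idx, W, H, trace)
    _, W, H, trace = best
    col = W.sum(axis=0)
    W = W / np.maximum(col, _EPS)
    H = H * col[:, None]
    names = [f"S{i + 1}" for i in range(k)]
    return SignatureSet(
        W=pd.DataFrame(W, index=list(counts.columns), columns=names),
        H=pd.DataFrame(H, index=names, columns=list(counts.index)),
        k=k,
        objective_trace=np.asarray(trace),
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def read_catalog_tsv(path) -> pd.DataFrame:
    """Reference catalog: first column context labels, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.reindex(CONTEXT_CLASSES)


def cosine_match(signatures: SignatureSet, catalog: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best catalog match per extracted signature, plus the full
    similarity matrix (signatures x catalog entries)."""
    if catalog.shape[1] == 0:
        raise ValueError("empty reference catalog")
    cat = catalog.reindex(signatures.W.index).to_numpy(dtype=float)
    sim = np.array([
        [cosine_similarity(signatures.W[name].to_numpy(), cat[:, j])
         for j in range(cat.shape[1])]
        for name in signatures.signature_names
    ])
    sim_df = pd.DataFrame(sim, index=signatures.signature_names, columns=list(catalog.columns))
    best = pd.DataFrame({
        "signature": signatures.signature_names,
        "best_match": sim_df.idxmax(axis=1).to_numpy(),
        "cosine": sim_df.max(axis=1).to_numpy(),
    })
    return best, sim_df


def pair_signatures(W: pd.DataFrame, truth: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy best-match pairing of extracted columns against planted
    signatures; returns (extracted index, truth index, cosine) triples."""
    k, kt = W.shape[1], truth.shape[1]
    sims = np.array([
        [cosine_similarity(W.iloc[:, i].to_numpy(), truth[:, j]) for j in range(kt)]
        for i in range(k)
    ])
    pairs = []
    used_i, used_j = set(), set()
    for _ in range(min(k, kt)):
        masked = sims.copy()
        for i in used_i:
            masked[i, :] = -np.inf
        for j in used_j:
            masked[:, j] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        pairs.append((int(i), int(j), float(sims[i, j])))
        used_i.add(int(i))
        used_j.add(int(j))
    return pairs
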