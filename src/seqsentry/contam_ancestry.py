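"""Joint contamination-fraction and ancestry estimation from marker pileups.

Each marker's expected alternate-allele frequency for an individual is its
panel mean dosage plus a principal-component projection, halved.  Reads at
a marker are modeled as a two-person mixture: with probability alpha a
read comes from the contaminant's genotype, otherwise from the intended
sample's; genotypes follow Hardy-Weinberg at each person's
individual-specific frequency.  The likelihood is maximized over alpha
(in [0, 0.5]) and the PC coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .variant_qc import PileupSite

EPS_F = 1e-4
ALPHA_GRID = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5)
MIN_SITES_WARN = 100


@dataclass
class SvdPanel:
    """Per-marker mean dosage + PC loadings, with reference coordinates."""

    mu: np.ndarray                       # (n,) mean alt dosage in [0, 2]
    loadings: np.ndarray                 # (n, K)
    marker_names: list[str] = field(default_factory=list)
    ref_samples: list[str] = field(default_factory=list)
    ref_pops: list[str] = field(default_factory=list)
    ref_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_markers(self) -> int:
        return len(self.mu)

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]

    def population_centroids(self) -> dict[str, np.ndarray]:
        cents: dict[str, list[np.ndarray]] = {}
        for pop, coord in zip(self.ref_pops, self.ref_coords):
            cents.setdefault(pop, []).append(coord)
        return {p: np.mean(v, axis=0) for p, v in cents.items()}


@dataclass
class ContamEstimate:
    alpha: float
    pc: np.ndarray
    pc2: np.ndarray
    loglik: float
    n_sites: int
    converged: bool
    population: str | None = None
    warnings: list[str] = field(default_factory=list)


def site_af(pc: np.ndarray, panel: SvdPanel, i: int) -> float:
    """Individual-specific alternate-allele frequency at marker i."""
    f = (panel.mu[i] + panel.loadings[i] @ np.asarray(pc)) / 2.0
    return float(np.clip(f, EPS_F, 1.0 - EPS_F))


def site_af_all(pc: np.ndarray, panel: SvdPanel) -> np.ndarray:
    f = (panel.mu + panel.loadings @ np.asarray(pc)) / 2.0
    return np.clip(f, EPS_F, 1.0 - EPS_F)


def _hwe_log(f: np.ndarray) -> np.ndarray:
    """(3, n) log HWE genotype probabilities at frequencies f."""
    return np.log(np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2]))


@dataclass
class _FlatPileups:
    """Pileups flattened for vectorized likelihood evaluation."""

    site_of_read: np.ndarray    # (R,) index into used sites
    p_ref: np.ndarray           # (R,) P(base | ref allele)
    p_alt: np.ndarray           # (R,) P(base | alt allele)
    used_sites: np.ndarray      # indices into the panel
    read_starts: np.ndarray     # (S+1,) reduceat boundaries

    @classmethod
    def build(cls, pileups: list[PileupSite]) -> "_FlatPileups":
        site_idx, p_ref, p_alt = [], [], []
        used = []
        starts = [0]
        for s in pileups:
            if s.depth == 0:
                continue
            used.append(s.marker_index)
            e = 10.0 ** (-s.quals / 10.0)
            p_ref.append(np.where(s.base_ids == 0, 1 - e, e / 3.0))
            p_alt.append(np.where(s.base_ids == 1, 1 - e, e / 3.0))
            site_idx.append(np.full(s.depth, len(used) - 1))
            starts.append(starts[-1] + s.depth)
        if not used:
            raise ValueError("no overlapping covered sites for contamination model")
        return cls(np.concatenate(site_idx), np.concatenate(p_ref),
                   np.concatenate(p_alt), np.asarray(used),
                   np.asarray(starts))


def _loglik_flat(flat: _FlatPileups, alpha: float, pc: np.ndarray,
                 pc2: np.ndarray, panel: SvdPanel) -> float:
    f1 = site_af_all(pc, panel)[flat.used_sites]
    f2 = site_af_all(pc2, panel)[flat.used_sites]
    logw1 = _hwe_log(f1)      # (3, S)
    logw2 = _hwe_log(f2)
    # per-read P(base | g) for g in 0,1,2
    pg = np.stack([flat.p_ref,
                   0.5 * (flat.p_ref + flat.p_alt),
                   flat.p_alt])               # (3, R)
    n_sites = len(flat.used_sites)
    terms = np.empty((3, 3, n_sites))
    bounds = flat.read_starts[:-1]
    for g1 in range(3):
        for g2 in range(3):
            mix = (1.0 - alpha) * pg[g1] + alpha * pg[g2]
            logmix = np.log(np.maximum(mix, 1e-300))
            terms[g1, g2] = np.add.reduceat(logmix, bounds)
    total = terms + logw1[:, None, :] + logw2[None, :, :]
    return float(logsumexp(total.reshape(9, n_sites), axis=0).sum())


def mixture_loglik(pileups: list[PileupSite], alpha: float, pc: np.ndarray,
                   pc2: np.ndarray, panel: SvdPanel) -> float:
    """Log-likelihood of the two-person mixture over all covered sites."""
    flat = _FlatPileups.build(pileups)
    return _loglik_flat(flat, alpha, np.asarray(pc, float),
                        np.asarray(pc2, float), panel)


def mixture_loglik_bruteforce(pileups: list[PileupSite], alpha: float,
                              pc: np.ndarray, pc2: np.ndarray,
                              panel: SvdPanel) -> float:
    """Plain-loop oracle: explicit 9-term genotype sum per site."""
    total = 0.0
    for s in pileups:
        if s.depth == 0:
            continue
        f1 = site_af(pc, panel, s.marker_index)
        f2 = site_af(pc2, panel, s.marker_index)
        w1 = [(1 - f1) ** 2, 2 * f1 * (1 - f1), f1 ** 2]
        w2 = [(1 - f2) ** 2, 2 * f2 * (1 - f2), f2 ** 2]
        site_lik = 0.0
        for g1 in range(3):
            for g2 in range(3):
                lik = w1[g1] * w2[g2]
                for b, q in zip(s.base_ids, s.quals):
                    e = 10.0 ** (-q / 10.0)
                    pr = (1 - e) if b == 0 else e / 3.0
                    pa = (1 - e) if b == 1 else e / 3.0
                    pb1 = (g1 / 2.0) * pa + (1 - g1 / 2.0) * pr
                    pb2 = (g2 / 2.0) * pa + (1 - g2 / 2.0) * pr
                    lik *= (1 - alpha) * pb1 + alpha * pb2
                site_lik += lik
        total += np.log(site_lik)
    return float(total)


def estimate(pileups: list[PileupSite], panel: SvdPanel,
             share_pc: bool = True) -> ContamEstimate:
    """Coarse grid over (alpha, pc) then Nelder-Mead refinement."""
    flat = _FlatPileups.build(pileups)
    warnings = []
    if len(flat.used_sites) < MIN_SITES_WARN:
        warnings.append(f"only {len(flat.used_sites)} usable sites; "
                        "estimate may be unstable")
    k = panel.n_pc
    pc_grid = [np.zeros(k)]
    cents = panel.population_centroids()
    pc_grid.extend(cents.values())
    if len(panel.ref_coords):
        pc_grid.append(panel.ref_coords.mean(axis=0))

    best = None
    for a in ALPHA_GRID:
        for pc in pc_grid:
            ll = _loglik_flat(flat, a, pc, pc, panel)
            if best is None or ll > best[0]:
                best = (ll, a, pc)
    _, a0, pc0 = best

    if share_pc:
        x0 = np.concatenate([[a0], pc0])
        bounds = [(0.0, 0.5)] + [(None, None)] * k

        def neg(x):
            return -_loglik_flat(flat, x[0], x[1:], x[1:], panel)
    else:
        x0 = np.concatenate([[a0], pc0, pc0])
        bounds = [(0.0, 0.5)] + [(None, None)] * (2 * k)

        def neg(x):
            return -_loglik_flat(flat, x[0], x[1 : 1 + k], x[1 + k :], panel)

    res = minimize(neg, x0, method="Nelder-Mead", bounds=bounds,
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    alpha = float(np.clip(res.x[0], 0.0, 0.5))
    pc = res.x[1 : 1 + k]
    pc2 = pc if share_pc else res.x[1 + k :]
    est = ContamEstimate(alpha=alpha, pc=pc, pc2=np.asarray(pc2),
                         loglik=float(-res.fun), n_sites=len(flat.used_sites),
                         converged=bool(res.success), warnings=warnings)
    if cents:
        est.population = assign_ancestry(pc, panel)[0]
    return est


def assign_ancestry(pc: np.ndarray, panel: SvdPanel) -> tuple[str, dict[str, float]]:
    """Nearest population centroid in PC space; ties break alphabetically."""
    cents = panel.population_centroids()
    if not cents:
        raise ValueError("panel has no reference population labels")
    dists = {p: float(np.linalg.norm(np.asarray(pc) - c))
             for p, c in sorted(cents.items())}
    label = min(dists, key=lambda p: (dists[p], p))
    return label, dists


# ---------------------------------------------------------------------------
# panel I/O (tab-delimited)


def write_svd_panel(panel: SvdPanel, prefix: str) -> tuple[str, str]:
    markers_path, coords_path = f"{prefix}.svd.tsv", f"{prefix}.coords.tsv"
    k = panel.n_pc
    with open(markers_path, "w") as fh:
        cols = "\t".join(f"L{j + 1}" for j in range(k))
        fh.write(f"marker\tmu\t{cols}\n")
        for i in range(panel.n_markers):
            name = panel.marker_names[i] if panel.marker_names else str(i)
            row = "\t".join(f"{x:.6g}" for x in panel.loadings[i])
            fh.write(f"{name}\t{panel.mu[i]:.6g}\t{row}\n")
    with open(coords_path, "w") as fh:
        cols = "\t".join(f"pc{j + 1}" for j in range(k))
        fh.write(f"sample\tpop\t{cols}\n")
        for s, p, coord in zip(panel.ref_samples, panel.ref_pops, panel.ref_coords):
            row = "\t".join(f"{x:.6g}" for x in coord)
            fh.write(f"{s}\t{p}\t{row}\n")
    return markers_path, coords_path


def read_svd_panel(prefix: str) -> SvdPanel:
    import pandas as pd

    m = pd.read_csv(f"{prefix}.svd.tsv", sep="\t")
    lcols = [c for c in m.columns if c.startswith("L")]
    coords = pd.read_csv(f"{prefix}.coords.tsv", sep="\t")
    pccols = [c for c in coords.columns if c.startswith("pc")]
    return SvdPanel(
        mu=m["mu"].to_numpy(float),
        loadings=m[lcols].to_numpy(float),
        marker_names=m["marker"].astype(str).tolist(),
        ref_samples=coords["sample"].astype(str).tolist(),
        ref_pops=coords["pop"].astype(str).tolist(),
        ref_coords=coords[pccols].to_numpy(float),
    )
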