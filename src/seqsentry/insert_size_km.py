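"""Censoring-corrected insert-size distribution estimation.

Short flanking contigs truncate large fragments: a pair with only one mate
inside a contig reveals a lower bound (its maximal insert size) but not
the insert itself.  Treating observed inserts as events and maximal insert
sizes of single-end-mapped pairs as right-censoring times, the
product-limit (Kaplan-Meier) estimator recovers the unbiased distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mini_aligner import PairRecord
from .panel_builder import ReducedReference


@dataclass(frozen=True)
class InsertTuple:
    """(observed insert, maximal insert of the forward mate, maximal insert
    of the reverse mate); missing values are None."""

    t_o: int | None
    t_l: int | None
    t_r: int | None

    def __post_init__(self) -> None:
        if self.t_o is not None:
            if self.t_l is None or self.t_r is None:
                raise ValueError("fully observed tuple needs both maximal inserts")
            if self.t_o > min(self.t_l, self.t_r):
                raise ValueError("observed insert exceeds a maximal insert")
        else:
            if (self.t_l is None) == (self.t_r is None):
                raise ValueError("single-end tuple needs exactly one maximal insert")

    @property
    def observed(self) -> bool:
        return self.t_o is not None

    @property
    def censor_time(self) -> int:
        if self.observed:
            raise ValueError("observed tuple has no censoring time")
        return self.t_l if self.t_l is not None else self.t_r  # type: ignore


def build_tuples(pairs: list[PairRecord], ref: ReducedReference,
                 min_mapq: int = 20) -> list[InsertTuple]:
    """Insert tuples from classified pairs.

    Proper pairs are fully observed; the forward mate's maximal insert runs
    to the contig's right end and the reverse mate's to its left end, so
    t_o = t_l + t_r - contig_length.  Pairs with exactly one adequately
    mapped mate are censored at that mate's maximal insert size.  Improper
    both-mapped pairs are discarded.
    """
    tuples: list[InsertTuple] = []
    for pair in pairs:
        m1, m2 = pair.mate1, pair.mate2
        if pair.proper:
            left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
            clen = len(ref.contigs[left.contig].seq)
            t_l = clen - left.start
            t_r = right.end
            tuples.append(InsertTuple(pair.t_o, t_l, t_r))
            continue
        mapped = [a for a in (m1, m2) if a.mapped and a.mapq >= min_mapq]
        if len(mapped) != 1:
            continue  # unmapped or improper both-mapped pair
        a = mapped[0]
        clen = len(ref.contigs[a.contig].seq)
        if a.strand == "+":
            tuples.append(InsertTuple(None, clen - a.start, None))
        else:
            tuples.append(InsertTuple(None, None, a.end))
    return tuples


@dataclass
class StepCDF:
    """Right-continuous step CDF on a finite grid."""

    times: np.ndarray   # strictly increasing
    values: np.ndarray  # F(times[i]), non-decreasing

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return vals

    @property
    def total_mass(self) -> float:
        return float(self.values[-1]) if len(self.values) else 0.0


@dataclass
class KmCurve:
    times: np.ndarray        # pooled event/censoring grid tau_j
    events: np.ndarray       # o_j
    censored: np.ndarray     # c_j
    risk: np.ndarray         # Y(tau_j)
    survival: np.ndarray     # S_km(tau_j)
    defective: bool          # largest time censored -> F never reaches 1

    @property
    def cdf(self) -> StepCDF:
        return StepCDF(self.times, 1.0 - self.survival)

    def normalized_cdf(self) -> StepCDF:
        """CDF renormalized to total mass 1 (summary statistics only)."""
        f = 1.0 - self.survival
        top = f[-1]
        return StepCDF(self.times, f / top if top > 0 else f)

    def quantile(self, q: float) -> float:
        f = self.normalized_cdf()
        idx = int(np.searchsorted(f.values, q, side="left"))
        idx = min(idx, len(f.times) - 1)
        if idx == 0 or f.values[idx] == q:
            return float(f.times[idx])
        # linear interpolation between adjacent grid steps
        t0, t1 = f.times[idx - 1], f.times[idx]
        v0, v1 = f.values[idx - 1], f.values[idx]
        if v1 == v0:
            return float(t1)
        return float(t0 + (q - v0) / (v1 - v0) * (t1 - t0))

    def summary(self) -> dict:
        return {
            "median": self.quantile(0.5),
            "p05": self.quantile(0.05),
            "p95": self.quantile(0.95),
            "defective": self.defective,
            "n_events": int(self.events.sum()),
            "n_censored": int(self.censored.sum()),
        }


def _event_censor_times(tuples: list[InsertTuple],
                        censor_policy: str) -> tuple[np.ndarray, np.ndarray]:
    """Split tuples into event and censoring-time arrays.

    ``censor_policy`` controls which single-end-mapped pairs enter as
    censorings:

    * ``"left"`` (default): only pairs whose forward mate mapped (t_l).
      Anchoring every fragment at its leftmost read makes the sample a
      coherent risk population — every fully observed pair belongs to it —
      and yields an unbiased product-limit estimate.
    * ``"both"``: t_l or t_r, whichever is present.  This uses all
      single-end pairs but gives every fragment two chances to appear as a
      censoring against one chance as an event, inflating the risk set and
      biasing the estimate low; retained for comparison.
    """
    if censor_policy not in ("left", "both"):
        raise ValueError("censor_policy must be 'left' or 'both'")
    ev = np.array([t.t_o for t in tuples if t.observed], dtype=float)
    if censor_policy == "left":
        ce = np.array([t.t_l for t in tuples
                       if not t.observed and t.t_l is not None], dtype=float)
    else:
        ce = np.array([t.censor_time for t in tuples if not t.observed],
                      dtype=float)
    if len(ev) == 0:
        raise ValueError("no properly paired reads: cannot estimate insert sizes")
    return ev, ce


def _km_from_times(ev: np.ndarray, ce: np.ndarray) -> KmCurve:
    times = np.unique(np.concatenate([ev, ce]))
    o = np.array([(ev == t).sum() for t in times], dtype=np.int64)
    c = np.array([(ce == t).sum() for t in times], dtype=np.int64)
    total = o + c
    risk = total[::-1].cumsum()[::-1]  # Y(tau_j) = sum_{k>=j} (o_k + c_k)
    # telescoping product: between censorings Y drops exactly by o, so the
    # partial product collapses to a single exact ratio
    surv = np.empty(len(times))
    seg_start_y = float(risk[0]) if len(risk) else 0.0
    s_prev = 1.0
    for j in range(len(times)):
        surv[j] = s_prev * (risk[j] - o[j]) / seg_start_y
        if c[j] > 0:
            s_prev = surv[j]
            seg_start_y = float(risk[j] - o[j] - c[j])
            if seg_start_y <= 0:
                seg_start_y = 1.0  # no one left at risk; S stays put
    defective = bool(surv[-1] > 1e-12)
    return KmCurve(times, o, c, risk, surv, defective)


def km_estimate(tuples: list[InsertTuple],
                censor_policy: str = "left") -> KmCurve:
    """Product-limit estimator over the pooled event/censoring grid.

    Risk set Y(t) counts every contributing tuple whose event or censoring
    time is >= t (events precede censorings at ties); S multiplies
    (1 - o_j/Y_j) over event times up to t.  See
    :func:`_event_censor_times` for the censoring policy.
    """
    ev, ce = _event_censor_times(tuples, censor_policy)
    return _km_from_times(ev, ce)


def km_estimate_ipcw(tuples: list[InsertTuple],
                     censor_policy: str = "left") -> StepCDF:
    """Inverse-probability-of-censoring-weighted reformulation.

    Weights each observed insert by the Kaplan-Meier estimate of the
    censoring survival just before its event time; algebraically identical
    to the product-limit curve and used as a cross-check.
    """
    ev, ce = _event_censor_times(tuples, censor_policy)
    ev = np.sort(ev)
    n = len(ev) + len(ce)
    times = np.unique(np.concatenate([ev, ce]))
    o = np.array([(ev == t).sum() for t in times], dtype=np.int64)
    c = np.array([(ce == t).sum() for t in times], dtype=np.int64)
    risk = (o + c)[::-1].cumsum()[::-1]
    # censorings occur after events at ties, so their risk set drops o_j
    factors = np.where(c > 0, 1.0 - c / np.maximum(risk - o, 1), 1.0)
    g = np.cumprod(factors)  # G(tau_j), right-continuous
    # G just before each event time
    g_minus = np.ones(len(ev))
    for i, t in enumerate(ev):
        j = np.searchsorted(times, t) - 1
        g_minus[i] = g[j] if j >= 0 else 1.0
    uniq_ev = np.unique(ev)
    f_vals = np.zeros(len(uniq_ev))
    acc = 0.0
    k = 0
    for i, t in enumerate(ev):
        acc += 1.0 / (n * g_minus[i])
        if i + 1 == len(ev) or ev[i + 1] != t:
            f_vals[k] = acc
            k += 1
    return StepCDF(uniq_ev, np.minimum(f_vals, 1.0))


def naive_estimate(tuples: list[InsertTuple]) -> StepCDF:
    """ECDF over the fully observed tuples only (the biased estimator)."""
    ev = np.sort(np.array([t.t_o for t in tuples if t.observed], dtype=float))
    if len(ev) == 0:
        raise ValueError("no properly paired reads: cannot estimate insert sizes")
    times, counts = np.unique(ev, return_counts=True)
    return StepCDF(times, counts.cumsum() / len(ev))


def distribution_distance(f1: StepCDF, f2: StepCDF) -> tuple[float, float]:
    """(Kolmogorov-Smirnov D, normalized Wasserstein-1 W) between step CDFs.

    W integrates |F1-F2| exactly over the pooled step grid after rescaling
    the time axis to [0,1] by the largest grid value, making it scale-free.
    """
    grid = np.unique(np.concatenate([f1.times, f2.times]))
    v1, v2 = f1(grid), f2(grid)
    d = float(np.max(np.abs(v1 - v2)))
    if len(grid) < 2:
        return d, 0.0
    scale = float(grid[-1])
    widths = np.diff(grid)
    w = float(np.sum(np.abs(v1 - v2)[:-1] * widths) / scale)
    return d, w


def write_curve_tsv(curve: KmCurve, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("t\tevents\tcensored\trisk\tsurvival\tcdf\n")
        for i in range(len(curve.times)):
            fh.write(f"{curve.times[i]:g}\t{curve.events[i]}\t{curve.censored[i]}"
                     f"\t{curve.risk[i]}\t{curve.survival[i]:.10g}"
                     f"\t{1.0 - curve.survival[i]:.10g}\n")
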