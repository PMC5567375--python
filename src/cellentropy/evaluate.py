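"""Grid evaluation of all entropy-rate surfaces, tabular export, comparison.

The five entropy-rate components live on two lattices: the internal ones on
the cell interior ``x in [eps L, (1-eps) L]`` (the walls are excluded because
T -> 0 there) and the external ones on the intercellular gap ``[L, L+g]``.
Time is log-spaced over ``[t_min, t_max]`` to resolve the fast early decay.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import internal
from .config import CaseStudy, GridSpec
from .thermal import SeriesControl

INTERNAL_COMPONENTS = ("riQ", "riD", "rir", "ri_total")
EXTERNAL_COMPONENTS = ("reQ", "re_exch", "re_total")


@dataclass
class RateField:
    """One entropy-rate surface r(x,t) with its lattice and provenance."""

    component: str
    x: np.ndarray          # m, strictly increasing
    t: np.ndarray          # s, strictly increasing
    values: np.ndarray     # J K^-1 m^-3 s^-1, shape (nx, nt)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("lattice axes must be strictly increasing")
        if self.values.shape != (self.x.size, self.t.size):
            raise ValueError("values must have shape (nx, nt)")

    def peak(self) -> tuple[float, float, float]:
        """(max value, x at max, t at max)."""
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.values[i, j]), float(self.x[i]), float(self.t[j])


def interior_lattice(case: CaseStudy, grid: GridSpec | None = None):
    """(x, t) arrays for the internal components."""
    grid = grid or case.grid
    L = case.geometry.L
    x = np.linspace(grid.x_min_frac * L, grid.x_max_frac * L, grid.nx)
    t = np.logspace(np.log10(grid.t_min), np.log10(grid.t_max), grid.nt)
    return x, t


def gap_lattice(case: CaseStudy, grid: GridSpec | None = None, nx_gap: int = 101):
    """(x, t) arrays for the external components, spanning the gap [L, L+g]."""
    grid = grid or case.grid
    L, g = case.geometry.L, case.geometry.gap
    x = np.linspace(L, L + g, nx_gap)
    t = np.logspace(np.log10(grid.t_min), np.log10(grid.t_max), grid.nt)
    return x, t


def evaluate_case(case: CaseStudy, grid: GridSpec | None = None,
                  ctrl: SeriesControl | None = None) -> dict[str, RateField]:
    """Evaluate all seven entropy-rate surfaces for one case study.

    Returns a dict keyed by component label; ``ri_total`` / ``re_total`` are
    pointwise sums of their parts.
    """
    grid = grid or case.grid
    if ctrl is None:
        ctrl = SeriesControl(n_terms=grid.n_terms, tail_tol=grid.tol)
    meta = {
        "case": case.label,
        "T0_K": case.env.T0,
        "n_terms": ctrl.n_terms,
        "config_hash": case.config_hash(),
    }
    xi, ti = interior_lattice(case, grid)
    xe, te = gap_lattice(case, grid)
    fields: dict[str, RateField] = {}
    for comp in ("riQ", "riD", "rir"):
        vals = internal.mixture_rate(case, comp, xi[:, None], ti[None, :], ctrl)
        fields[comp] = RateField(comp, xi, ti, np.broadcast_to(vals, (xi.size, ti.size)).copy(), dict(meta))
    fields["ri_total"] = RateField(
        "ri_total", xi, ti,
        fields["riQ"].values + fields["riD"].values + fields["rir"].values,
        dict(meta),
    )
    for comp in ("reQ", "re_exch"):
        vals = internal.mixture_rate(case, comp, xe[:, None], te[None, :], ctrl)
        fields[comp] = RateField(comp, xe, te, np.broadcast_to(vals, (xe.size, te.size)).copy(), dict(meta))
    fields["re_total"] = RateField(
        "re_total", xe, te,
        fields["reQ"].values + fields["re_exch"].values,
        dict(meta),
    )
    return fields


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

_HEADER = ("x_m", "t_s", "value_J_per_K_m3_s")


def write_rate_table(rate_field: RateField, path) -> None:
    """Write one surface as delimited text with a comment-line metadata block."""
    xg, tg = np.meshgrid(rate_field.x, rate_field.t, indexing="ij")
    df = pd.DataFrame({
        _HEADER[0]: xg.ravel(),
        _HEADER[1]: tg.ravel(),
        _HEADER[2]: rate_field.values.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"# component: {rate_field.component}\n")
        for k, v in rate_field.meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_rate_table(path) -> RateField:
    """Read back a surface written by :func:`write_rate_table`."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = io.StringIO()
    for line in lines:
        if line.startswith("#"):
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
        else:
            body.write(line)
    body.seek(0)
    df = pd.read_csv(body, float_precision="round_trip")
    if tuple(df.columns) != _HEADER:
        raise ValueError(f"unexpected table header {tuple(df.columns)}")
    x = np.unique(df[_HEADER[0]].to_numpy())
    t = np.unique(df[_HEADER[1]].to_numpy())
    values = df[_HEADER[2]].to_numpy().reshape(x.size, t.size)
    component = meta.pop("component", "unknown")
    return RateField(component, x, t, values, meta)


# ---------------------------------------------------------------------------
# normal vs cancer comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonSummary:
    """Peak/mean values per component for two cases, and their ratios.

    ``band_ok`` flags whether the peak ratio of the first over the second
    case lies in the loose order-of-magnitude band [10, 1000] claimed for
    the diffusion and reaction terms; the heat-release contrast is reported
    without a band (its reference evaluation points are not fixed by the
    model).
    """

    label_a: str
    label_b: str
    peaks: dict
    means: dict
    peak_ratio: dict
    mean_ratio: dict
    peak_location: dict
    band_ok: dict

    def summary_lines(self) -> list[str]:
        out = [f"comparison: {self.label_a} vs {self.label_b}"]
        for comp in self.peak_ratio:
            out.append(
                f"  {comp:9s} peak {self.label_a}={self.peaks[comp][0]:.4g} "
                f"{self.label_b}={self.peaks[comp][1]:.4g} "
                f"ratio={self.peak_ratio[comp]:.4g} mean_ratio={self.mean_ratio[comp]:.4g}"
            )
        for comp, ok in self.band_ok.items():
            out.append(f"  band [10,1000] for {comp} peak ratio: {'ok' if ok else 'VIOLATED'}")
        return out


def compare_report(case_a: CaseStudy, case_b: CaseStudy,
                   grid: GridSpec | None = None) -> ComparisonSummary:
    """Evaluate both cases on their default lattices and compare components."""
    fa = evaluate_case(case_a, grid)
    fb = evaluate_case(case_b, grid)
    peaks, means, pratio, mratio, ploc, band_ok = {}, {}, {}, {}, {}, {}
    for comp in internal.COMPONENTS:
        pa, xa, ta = fa[comp].peak()
        pb, xb, tb = fb[comp].peak()
        peaks[comp] = (pa, pb)
        means[comp] = (float(fa[comp].values.mean()), float(fb[comp].values.mean()))
        pratio[comp] = pa / pb if pb != 0 else np.inf
        mratio[comp] = (means[comp][0] / means[comp][1]
                        if means[comp][1] != 0 else np.inf)
        ploc[comp] = ((xa, ta), (xb, tb))
    for comp in ("riD", "rir"):
        band_ok[comp] = 10.0 <= pratio[comp] <= 1000.0
    return ComparisonSummary(case_a.label, case_b.label, peaks, means,
                             pratio, mratio, ploc, band_ok)
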