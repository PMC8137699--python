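"""Chemical-shift referencing, predicted-spectrum aggregation and RMSE ranking.

Computed isotropic shieldings are converted to chemical shifts by ordinary
least squares against experimentally assigned shifts (shift = a*sigma + b,
fitted per element).  Predicted spectra are sums of per-proton Gaussians;
motif-conditional spectra partition the donor-proton records by motif and sum
exactly to the unconditional spectrum.  Candidate structures are ranked by
per-element RMSE between their computed shifts and the experimental
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ShiftRecord",
    "ReferencingModel",
    "SpectrumHistogram",
    "CandidateStructure",
    "fit_referencing",
    "apply_referencing",
    "aggregate_spectrum",
    "motif_conditional_spectra",
    "population_above",
    "shift_rmse",
    "rank_candidates",
]


@dataclass(frozen=True)
class ShiftRecord:
    """A per-atom predicted shielding or chemical shift tied to one snapshot."""

    atom_id: int
    snapshot_id: int
    element: str
    site_label: str
    value_ppm: float
    kind: str  # "shielding" | "shift"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value_ppm):
            raise ValueError("shift/shielding value must be finite")
        if self.kind not in ("shielding", "shift"):
            raise ValueError(f"unknown record kind {self.kind!r}")


@dataclass(frozen=True)
class ReferencingModel:
    """Affine shielding-to-shift map for one element: shift = slope*sigma + intercept."""

    slope: float
    intercept: float
    element: str
    rmse_ppm: float
    n_points: int

    def predict(self, shielding: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(shielding, dtype=float) + self.intercept


@dataclass
class SpectrumHistogram:
    """A binned spectrum: Gaussian-broadened stick positions on a ppm grid."""

    bin_edges: np.ndarray
    intensities: np.ndarray
    normalization: str  # "per_proton" | "unit_area"
    broadening_ppm: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < -1e-12).any():
            raise ValueError("spectrum intensities must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def integral(self) -> float:
        return float(self.intensities.sum() * self.bin_width)

    def mean_ppm(self) -> float:
        w = self.intensities.sum()
        return float((self.bin_centers * self.intensities).sum() / w) if w > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ppm": self.bin_centers, "intensity": self.intensities})


@dataclass
class CandidateStructure:
    """A trial structure's computed shifts: element -> site label -> ppm."""

    candidate_id: str
    shifts: dict[str, dict[str, float]]
    energy_per_molecule: float | None = None


# ---------------------------------------------------------------------------
# referencing
# ---------------------------------------------------------------------------


def fit_referencing(
    shieldings: list[ShiftRecord],
    experimental: dict[str, float],
    element: str,
) -> ReferencingModel:
    """OLS of experimental shift on computed shielding, matched by site label.

    Repeated sites (several snapshots) are averaged before fitting so each
    assigned site carries equal weight.
    """
    per_site: dict[str, list[float]] = {}
    for rec in shieldings:
        if rec.element != element or rec.kind != "shielding":
            continue
        if rec.site_label in experimental:
            per_site.setdefault(rec.site_label, []).append(rec.value_ppm)
    if len(per_site) < 2:
        raise ValueError(
            f"need >=2 matched sites to fit the {element} referencing, got {len(per_site)}"
        )
    sigma = np.array([np.mean(v) for v in per_site.values()])
    delta = np.array([experimental[k] for k in per_site.keys()])
    if np.ptp(sigma) == 0.0:
        raise ValueError("all shieldings identical; referencing slope undefined")
    res = stats.linregress(sigma, delta)
    pred = res.slope * sigma + res.intercept
    rmse = float(np.sqrt(np.mean((pred - delta) ** 2)))
    return ReferencingModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        element=element,
        rmse_ppm=rmse,
        n_points=len(sigma),
    )


def apply_referencing(
    model: ReferencingModel, records: list[ShiftRecord]
) -> list[ShiftRecord]:
    """Map shielding records to shift records, preserving order."""
    out = []
    for rec in records:
        if rec.element != model.element:
            raise ValueError(
                f"referencing model is for {model.element}, record is {rec.element}"
            )
        out.append(
            replace(rec, value_ppm=model.slope * rec.value_ppm + model.intercept, kind="shift")
        )
    return out


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _make_edges(
    values: np.ndarray, bin_width: float, ppm_range: tuple[float, float] | None
) -> np.ndarray:
    if ppm_range is None:
        lo = np.floor((values.min() - 4.0) / bin_width) * bin_width
        hi = np.ceil((values.max() + 4.0) / bin_width) * bin_width
    else:
        lo, hi = ppm_range
    n = max(int(round((hi - lo) / bin_width)), 1)
    return lo + bin_width * np.arange(n + 1)


def aggregate_spectrum(
    records: list[ShiftRecord],
    bin_width: float = 0.05,
    broadening_ppm: float = 0.25,
    normalization: str = "per_proton",
    ppm_range: tuple[float, float] | None = None,
) -> SpectrumHistogram:
    """Sum of unit-area Gaussians, one per proton record.

    Under ``per_proton`` normalization the spectrum integrates to the number
    of contributing protons; under ``unit_area`` it integrates to one.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    if bin_width <= 0 or broadening_ppm <= 0:
        raise ValueError("bin width and broadening must be positive")
    elements = {r.element for r in records}
    if len(elements) > 1:
        raise ValueError(f"records must be single-element, got {sorted(elements)}")
    kinds = {r.kind for r in records}
    if kinds != {"shift"}:
        raise ValueError("spectra are built from shift records; reference shieldings first")
    values = np.array([r.value_ppm for r in records], dtype=float)
    edges = _make_edges(values, bin_width, ppm_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z = (centers[None, :] - values[:, None]) / broadening_ppm
    dens = np.exp(-0.5 * z * z).sum(axis=0) / (broadening_ppm * np.sqrt(2.0 * np.pi))
    if normalization == "unit_area":
        dens = dens / len(values)
    elif normalization != "per_proton":
        raise ValueError(f"unknown normalization {normalization!r}")
    return SpectrumHistogram(
        bin_edges=edges,
        intensities=dens,
        normalization=normalization,
        broadening_ppm=broadening_ppm,
    )


def motif_conditional_spectra(
    records: list[ShiftRecord],
    motif_assignments: dict[tuple[int, int], str],
    bin_width: float = 0.05,
    broadening_ppm: float = 0.25,
    ppm_range: tuple[float, float] | None = None,
) -> dict[str, SpectrumHistogram]:
    """Per-motif spectra on a shared grid; their sum equals the full spectrum.

    ``motif_assignments`` maps (snapshot_id, atom_id) of each donor proton to
    its canonical motif string; a record without an assignment is an error.
    """
    if not records:
        raise ValueError("no records")
    values = np.array([r.value_ppm for r in records], dtype=float)
    edges = _make_edges(values, bin_width, ppm_range)
    shared = (float(edges[0]), float(edges[-1]))
    groups: dict[str, list[ShiftRecord]] = {}
    for rec in records:
        key = (rec.snapshot_id, rec.atom_id)
        if key not in motif_assignments:
            raise ValueError(f"no motif assignment for record {key}")
        groups.setdefault(motif_assignments[key], []).append(rec)
    return {
        motif: aggregate_spectrum(
            recs,
            bin_width=bin_width,
            broadening_ppm=broadening_ppm,
            normalization="per_proton",
            ppm_range=shared,
        )
        for motif, recs in groups.items()
    }


def population_above(
    records: list[ShiftRecord],
    threshold: float = 11.0,
    group_by: dict[int, str] | None = None,
) -> dict[str, float]:
    """Fraction of shifts strictly above the threshold, per ensemble group.

    ``group_by`` maps snapshot_id to a group key (e.g. water content); when
    omitted, each record's source_tag is the group.
    """
    groups: dict[str, list[float]] = {}
    for rec in records:
        key = group_by[rec.snapshot_id] if group_by is not None else rec.source_tag
        groups.setdefault(key, []).append(rec.value_ppm)
    out = {}
    for key, vals in groups.items():
        if not vals:
            raise ValueError(f"empty group {key!r}")
        arr = np.asarray(vals)
        out[key] = float((arr > threshold).mean())
    return out


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------


def shift_rmse(
    candidate: CandidateStructure,
    experimental: dict[str, float],
    element: str,
) -> float:
    """Root-mean-square error over assigned sites for one element."""
    comp = candidate.shifts.get(element, {})
    missing = [s for s in experimental if s not in comp]
    if missing:
        raise ValueError(
            f"candidate {candidate.candidate_id}: missing {element} sites {missing}"
        )
    diffs = np.array([comp[s] - experimental[s] for s in experimental], dtype=float)
    return float(np.sqrt(np.mean(diffs**2)))


def rank_candidates(
    candidates: list[CandidateStructure],
    experimental: dict[str, dict[str, float]],
    elements: list[str],
) -> pd.DataFrame:
    """Stable RMSE ranking of candidate structures.

    With a single element the sort key is that element's RMSE.  With several,
    per-element RMSEs are z-scored across candidates and averaged with equal
    weights, a simple documented stand-in for joint multi-element scoring.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    rows = []
    for cand in candidates:
        row: dict[str, object] = {"candidate_id": cand.candidate_id}
        for el in elements:
            row[f"rmse_{el}"] = shift_rmse(cand, experimental[el], el)
        if cand.energy_per_molecule is not None:
            row["energy_per_molecule"] = cand.energy_per_molecule
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(elements) == 1:
        df["score"] = df[f"rmse_{elements[0]}"]
    else:
        zs = []
        for el in elements:
            col = df[f"rmse_{el}"].to_numpy(dtype=float)
            sd = col.std(ddof=0)
            zs.append((col - col.mean()) / sd if sd > 0 else np.zeros_like(col))
        df["score"] = np.mean(zs, axis=0)
    df = df.sort_values("score", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
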