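"""Post-processing of flux samples into the reported quantities.

All reports operate on a mean flux-transport vector together with the
assembled system; flux orientations follow the canonical transport
directions (positive = into the tissue / into the cell / into the
mitochondria), so e.g. the astrocytic glutamine *efflux* to ECS is the
negative of the ECS->astrocyte-cytosol glutamine transport value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .catalog import ModelError
from .compartments import CELLS, ECS, cytosol_of, mitochondria_of
from .sampler import FluxSample
from .system import StoichiometricSystem


# ---------------------------------------------------------------------------
# subsampling


@dataclass(frozen=True)
class DirectionFilter:
    """Sign requirement on a flux or signed combination of fluxes.

    ``terms`` is a sequence of (flux_id, coefficient) pairs defining the
    net flux; ``required_sign`` is "positive" or "negative".
    """

    terms: tuple[tuple[str, float], ...]
    required_sign: str = "positive"

    @classmethod
    def on_flux(cls, flux_id: str, required_sign: str = "positive"):
        return cls(terms=((flux_id, 1.0),), required_sign=required_sign)

    def net_values(self, sample: FluxSample) -> np.ndarray:
        net = np.zeros(sample.n)
        for fid, coef in self.terms:
            net += coef * sample.column(fid)
        return net

    def mask(self, sample: FluxSample) -> np.ndarray:
        net = self.net_values(sample)
        if self.required_sign == "positive":
            return net > 0
        if self.required_sign == "negative":
            return net < 0
        raise ModelError(f"bad required_sign {self.required_sign!r}")


def nh4_into_astrocyte_filter() -> DirectionFilter:
    """Net ammonium flux from ECS into the astrocytic cytosol positive."""
    return DirectionFilter.on_flux(f"NH4+/{ECS}->{cytosol_of('astrocyte')}")


def subsample_by_direction(
    sample: FluxSample, filt: DirectionFilter, min_size: int = 50
) -> FluxSample:
    """Retain exactly the vectors whose net flux has the required sign.

    Stored vectors are never altered, only membership; the filter is
    recorded in the metadata.
    """
    mask = filt.mask(sample)
    kept = int(mask.sum())
    if kept < min_size:
        raise ModelError(
            f"direction filter {filt.terms} ({filt.required_sign}) retains "
            f"{kept} < {min_size} vectors"
        )
    meta = dict(sample.meta)
    filters = list(meta.get("filters", []))
    filters.append(
        {"terms": list(map(list, filt.terms)), "required_sign": filt.required_sign,
         "retained": kept, "of": sample.n}
    )
    meta["filters"] = filters
    return FluxSample(
        vectors=sample.vectors[mask], flux_index=list(sample.flux_index), meta=meta
    )


# ---------------------------------------------------------------------------
# smoothed histograms


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mean_marker: float
    flux_id: str = ""

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def smoothed_histogram(
    sample: FluxSample, flux_id: str, bandwidth: str | float = "auto",
    grid_points: int = 512,
) -> DensityCurve:
    """Gaussian kernel density estimate of one flux marginal.

    Bandwidth defaults to Silverman's rule; the grid is padded by three
    bandwidths beyond the sample range.  A zero-variance flux degenerates
    to a narrow spike (with a warning) rather than failing.
    """
    if sample.n < 100:
        raise ModelError("KDE requires at least 100 vectors")
    x = sample.column(flux_id)
    mean = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn(f"flux {flux_id!r} has zero variance; returning a spike")
        eps = max(1e-9, abs(mean) * 1e-6)
        grid = np.linspace(mean - 50 * eps, mean + 50 * eps, grid_points)
        dens = np.exp(-0.5 * ((grid - mean) / eps) ** 2) / (eps * np.sqrt(2 * np.pi))
        return DensityCurve(grid, dens, eps, mean, flux_id)
    bw = "silverman" if bandwidth == "auto" else bandwidth
    kde = gaussian_kde(x, bw_method=bw)
    h = float(kde.factor * sd)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    return DensityCurve(grid, kde(grid), h, mean, flux_id)


# ---------------------------------------------------------------------------
# report tables


@dataclass
class ReportTable:
    """Named scalar results with units and provenance."""

    title: str
    entries: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(
        self, name: str, value: float, unit: str = "umol/min",
        bounded: bool = True,
    ) -> None:
        """Add an entry; percentage entries that are structural shares of a
        whole (``bounded=True``) must lie in [0, 100], while percentages
        relative to a different base quantity may exceed 100."""
        if unit == "%":
            if value < -1e-9:
                raise ModelError(f"{name}: negative percentage {value}")
            if bounded and value > 100 + 1e-9:
                raise ModelError(f"{name}: percentage {value} outside [0, 100]")
        self.entries[name] = float(value)
        self.units[name] = unit

    def __getitem__(self, name: str) -> float:
        return self.entries[name]

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "entries": self.entries,
            "units": self.units,
            "provenance": self.provenance,
        }


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        raise ModelError(f"{name}: zero denominator")
    return num / den


def ammonium_glutamine_report(
    mean: np.ndarray, system: StoichiometricSystem
) -> ReportTable:
    """Glutamine/ammonium traffic between ECS and the cell compartments.

    The offset entry is the astrocytic glutamine efflux minus the ammonium
    influx into the astrocyte; the leucine entries quantify the amino
    nitrogen carried into the tissue and the astrocyte by leucine (one
    amino group per leucine).
    """
    v = system.value
    rpt = ReportTable("ammonium-glutamine traffic")
    gln_efflux = -v(mean, f"Gln/{ECS}->{cytosol_of('astrocyte')}")
    nh4_influx = v(mean, f"NH4+/{ECS}->{cytosol_of('astrocyte')}")
    rpt.add("gln_efflux_astrocyte_to_ECS", gln_efflux)
    rpt.add("gln_uptake_glutamatergic", v(mean, f"Gln/{ECS}->{cytosol_of('glutamatergic')}"))
    rpt.add("gln_uptake_GABAergic", v(mean, f"Gln/{ECS}->{cytosol_of('GABAergic')}"))
    rpt.add("nh4_efflux_glutamatergic", -v(mean, f"NH4+/{ECS}->{cytosol_of('glutamatergic')}"))
    rpt.add("nh4_efflux_GABAergic", -v(mean, f"NH4+/{ECS}->{cytosol_of('GABAergic')}"))
    rpt.add("nh4_influx_ECS_to_astrocyte", nh4_influx)
    rpt.add("gln_leak_ECS_to_blood", v(mean, f"Gln/{ECS}->blood"))
    rpt.add("leu_influx_blood_to_ECS", v(mean, f"Leu/blood->{ECS}"))
    rpt.add("leucine_nh4_into_astrocyte", v(mean, f"Leu/{ECS}->{cytosol_of('astrocyte')}"))
    rpt.add("offset_gln_efflux_minus_nh4_influx", gln_efflux - nh4_influx)
    return rpt


def gaba_precursor_report(
    mean: np.ndarray, system: StoichiometricSystem
) -> ReportTable:
    """Fates of glutamine and GABA in the GABAergic neuron."""
    v = system.value
    cyto, mito = cytosol_of("GABAergic"), mitochondria_of("GABAergic")
    gad = v(mean, f"GAD@{cyto}")
    pag = v(mean, f"PAG@{cyto}")
    gaba_to_mito = v(mean, f"GABA/{cyto}->{mito}")
    gaba_efflux = v(mean, f"GABA_vesicular/{cyto}->{ECS}")
    gln_uptake = v(mean, f"Gln/{ECS}->{cyto}")
    rpt = ReportTable("GABA precursor pathways (GABAergic neuron)")
    rpt.add("GAD_flux", gad)
    rpt.add("PAG_flux", pag)
    rpt.entries["GAD_over_PAG"] = _ratio(gad, pag, "GAD_over_PAG")
    rpt.units["GAD_over_PAG"] = "ratio"
    rpt.add("gaba_to_mitochondria_fraction",
            100.0 * _ratio(gaba_to_mito, gad, "gaba_to_mitochondria_fraction"), "%")
    rpt.add("gaba_shunt_share_of_SDH",
            100.0 * _ratio(v(mean, f"SSADH@{mito}"), v(mean, f"SDH@{mito}"),
                           "gaba_shunt_share_of_SDH"), "%")
    rpt.add("gln_influx_share_of_gaba_efflux",
            100.0 * _ratio(gln_uptake, gaba_efflux, "gln_influx_share_of_gaba_efflux"),
            "%", bounded=False)
    return rpt


def oxidation_fractions(
    mean: np.ndarray, system: StoichiometricSystem
) -> ReportTable:
    """Share of glutamine-derived glutamate oxidized via GDH, per neuron."""
    v = system.value
    rpt = ReportTable("glutamate oxidation fractions")
    for cell in ("glutamatergic", "GABAergic"):
        pag = v(mean, f"PAG@{cytosol_of(cell)}")
        gdh = v(mean, f"GDH@{mitochondria_of(cell)}")
        if pag <= 0:
            raise ModelError(f"{cell}: PAG flux {pag} <= 0")
        frac = 0.0 if gdh <= 0 else 100.0 * gdh / pag
        rpt.add(f"{cell}_gdh_over_pag", frac, "%", bounded=False)
    return rpt


def atp_turnover_shares(
    mean: np.ndarray, system: StoichiometricSystem
) -> ReportTable:
    """Mean ATP turnover per cell type (consumption side) and shares.

    A flux's contribution is its net cell-level ATP consumption rate
    max(0, -coef_ATP * u); intra-cell ATP transports cancel.  At steady
    state production equals consumption, so the consumption-side sum
    measures the cell's energy demand.
    """
    by_id = system.spec_by_id
    turnover = {cell: 0.0 for cell in CELLS}
    for j, fid in enumerate(system.flux_index):
        spec = by_id[fid]
        per_cell: dict[str, float] = {}
        for sp, coef in spec.species_stoichiometry.items():
            if sp.name != "ATP":
                continue
            cell = _cell_of(sp.compartment)
            if cell is not None:
                per_cell[cell] = per_cell.get(cell, 0.0) + coef
        for cell, net in per_cell.items():
            consumption = -net * mean[j]
            if consumption > 0:
                turnover[cell] += consumption
    total = sum(turnover.values())
    if total == 0:
        raise ModelError("zero total ATP turnover")
    rpt = ReportTable("ATP turnover by cell type")
    for cell in CELLS:
        rpt.add(f"{cell}_atp_turnover", turnover[cell])
        rpt.add(f"{cell}_share", 100.0 * turnover[cell] / total, "%")
    return rpt


def _cell_of(compartment: str) -> str | None:
    from .compartments import cell_of

    return cell_of(compartment)


def shuttle_report(mean: np.ndarray, system: StoichiometricSystem) -> ReportTable:
    """Astrocytic reactions liberating ammonium from alanine and leucine.

    In the astrocyte, reverse ALT deaminates alanine (negative flux in the
    Pyr+Glu -> Ala+AKG orientation) and forward mitochondrial BCAT
    deaminates leucine; GDH releases the ammonium which, together with the
    ECS influx, feeds glutamine synthetase.
    """
    v = system.value
    ast_c, ast_m = cytosol_of("astrocyte"), mitochondria_of("astrocyte")
    gdh = v(mean, f"GDH@{ast_m}")
    gs = v(mean, f"GS@{ast_c}")
    nh4_in = v(mean, f"NH4+/{ECS}->{ast_c}")
    rpt = ReportTable("astrocytic amino-group shuttle bookkeeping")
    rpt.add("ALT_astrocyte", v(mean, f"ALT@{ast_c}"))
    rpt.add("BCAT_astrocyte_mito", v(mean, f"BCAT@{ast_m}"))
    rpt.add("GDH_astrocyte", gdh)
    rpt.add("GS_astrocyte", gs)
    rpt.add("nh4_net_ECS_to_astrocyte", nh4_in)
    rpt.add("gdh_plus_influx_minus_gs", gdh + nh4_in - gs)
    rpt.entries["gdh_share_of_gs_ammonium"] = _ratio(
        gdh, gs, "gdh_share_of_gs_ammonium"
    )
    rpt.units["gdh_share_of_gs_ammonium"] = "ratio"
    return rpt


# ---------------------------------------------------------------------------
# invariant helpers


def steady_state_residuals(
    mean: np.ndarray,
    system: StoichiometricSystem,
    rhs: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    """Per-equation |A u - r| / sigma at a flux vector."""
    return np.abs(system.matrix @ mean - rhs) / sigma


def gdh_means(sample_or_mean, system: StoichiometricSystem) -> dict[str, float]:
    """GDH flux (mean) per cell type."""
    if isinstance(sample_or_mean, FluxSample):
        u = sample_or_mean.vectors.mean(axis=0)
    else:
        u = np.asarray(sample_or_mean)
    return {
        cell: system.value(u, f"GDH@{mitochondria_of(cell)}") for cell in CELLS
    }
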