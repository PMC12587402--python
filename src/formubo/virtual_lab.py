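"""Virtual laboratory: deterministic ground-truth response surfaces with
the qualitative structure of real mAb formulation screens, plus noisy
simulated raw assay data.

The surfaces encode the field's typical trends: raising pH improves
thermal stability (Tm) but erodes colloidal stability (kD); sorbitol
helps up to an intermediate optimum near 300 mM; arginine is strongly
detrimental to kD; retained monomer plateaus in the 90-100% band.  The
coefficients are synthetic fixtures chosen so the best achievable values
sit near realistic optimized magnitudes (Tm ~ 72 degC, kD ~ 44 mL/g);
they are not fitted to any measured data set.

``measure`` never shortcuts to the surface values: it synthesizes raw
instrument-style data (melt curve, DLS dilution series, agitation
concentrations) and pushes them through the assays module, so the whole
measurement pipeline is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import (
    DEFAULT_DLS_CONCENTRATIONS,
    DlsDilutionSeries,
    MeltCurve,
    fit_kd,
    retained_monomer,
    tm_from_curve,
)
from .chemistry import Formulation

__all__ = ["LabConfig", "Observation", "VirtualLab", "true_surfaces"]


@dataclass(frozen=True)
class LabConfig:
    """Noise levels and instrument-grid settings of the simulated lab.

    Replicate-to-replicate scatter: ``sd_tm`` shifts each replicate's melt
    midpoint (degC), ``sd_kd`` jitters each replicate series' underlying
    slope (mL/g), ``sd_rm`` perturbs the recovered supernatant
    concentration (RM percentage points).  ``dls_rel_sd`` is within-series
    multiplicative noise on each diffusion coefficient.
    """

    sd_tm: float = 0.2
    sd_kd: float = 1.5
    sd_rm: float = 2.0
    dls_rel_sd: float = 0.005
    n_replicates: int = 3
    melt_t_min: float = 25.0
    melt_t_max: float = 90.0
    melt_t_step: float = 0.5
    melt_baseline: float = 0.80
    melt_amplitude: float = 0.30
    melt_width: float = 2.0
    dls_d0: float = 60.0
    dls_concentrations: tuple[float, ...] = DEFAULT_DLS_CONCENTRATIONS
    rm_c_ref: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sd_tm, self.sd_kd, self.sd_rm, self.dls_rel_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def noiseless(self) -> "LabConfig":
        from dataclasses import replace

        return replace(self, sd_tm=0.0, sd_kd=0.0, sd_rm=0.0, dls_rel_sd=0.0)


@dataclass
class Observation:
    """A formulation with its (simulated or measured) objective vector."""

    formulation: Formulation
    tm: float
    kd: float
    rm: float
    iteration: int = -1
    route: str = ""
    replicates: dict = field(default_factory=dict)

    @property
    def objectives(self) -> np.ndarray:
        return np.array([self.tm, self.kd, self.rm])


def true_surfaces(formulation: Formulation, config: LabConfig | None = None) -> np.ndarray:
    """Noise-free ground-truth (Tm degC, kD mL/g, RM %) of a feasible
    formulation.

    Tm = 66 + 1.2 (pH - 4.5) + 3 s/(s+150) - 2 a/250
    kD = -25 + 18 (7.5 - pH) + 15 (2r - r^2) - 0.2 a,  r = s/324
    RM = min(100, 70 + 28 logistic(0.01 s - 0.03 a + 1))

    with s = sorbitol (mM), a = arginine (mM).  The kD sorbitol term peaks
    at s = 324 mM and its arginine slope is -0.2 mL/g per mM everywhere.
    """
    if not formulation.feasible:
        raise ValueError("true surfaces are defined on feasible formulations only")
    s, a, pH = formulation.sorbitol, formulation.arginine, formulation.pH
    tm = 66.0 + 1.2 * (pH - 4.5) + 3.0 * s / (s + 150.0) - 2.0 * a / 250.0
    r = s / 324.0
    kd = -25.0 + 18.0 * (7.5 - pH) + 15.0 * (2.0 * r - r * r) - 0.2 * a
    rm = min(100.0, 70.0 + 28.0 / (1.0 + np.exp(-(0.01 * s - 0.03 * a + 1.0))))
    return np.array([tm, kd, rm])


class VirtualLab:
    """Simulated measurement source producing Observation records through
    the real assay pipeline."""

    def __init__(self, config: LabConfig | None = None, rng: np.random.Generator | int | None = None):
        self.config = config if config is not None else LabConfig()
        self.rng = np.random.default_rng(rng)

    def true_surfaces(self, formulation: Formulation) -> np.ndarray:
        return true_surfaces(formulation, self.config)

    def simulate_melt_curve(self, tm_center: float) -> MeltCurve:
        cfg = self.config
        T = np.arange(cfg.melt_t_min, cfg.melt_t_max + cfg.melt_t_step / 2, cfg.melt_t_step)
        ratio = cfg.melt_baseline + cfg.melt_amplitude / (
            1.0 + np.exp(-(T - tm_center) / cfg.melt_width)
        )
        return MeltCurve(T, ratio)

    def simulate_dls_series(self, kd_true: float) -> DlsDilutionSeries:
        cfg = self.config
        c = np.asarray(cfg.dls_concentrations)
        D = cfg.dls_d0 * (1.0 + kd_true * 1e-3 * c)
        D = D * (1.0 + self.rng.normal(0.0, cfg.dls_rel_sd, size=len(c)))
        return DlsDilutionSeries(c, D)

    def measure(self, formulation: Formulation) -> Observation:
        """Simulate triplicate raw assay data at this formulation and run
        the assays module on it; replicate results are averaged."""
        cfg = self.config
        tm_true, kd_true, rm_true = true_surfaces(formulation, cfg)
        tms, kds, rms = [], [], []
        for _ in range(cfg.n_replicates):
            curve = self.simulate_melt_curve(tm_true + self.rng.normal(0.0, cfg.sd_tm))
            tms.append(tm_from_curve(curve))
            series = self.simulate_dls_series(kd_true + self.rng.normal(0.0, cfg.sd_kd))
            _, kd_fit, _ = fit_kd(series)
            kds.append(kd_fit)
            rm_target = rm_true + self.rng.normal(0.0, cfg.sd_rm)
            c_shaken = max(0.0, cfg.rm_c_ref * rm_target / 100.0)
            rms.append(retained_monomer(cfg.rm_c_ref, c_shaken))
        return Observation(
            formulation=formulation,
            tm=float(np.mean(tms)),
            kd=float(np.mean(kds)),
            rm=float(np.mean(rms)),
            replicates={"tm": tms, "kd": kds, "rm": rms},
        )
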