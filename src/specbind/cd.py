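"""Far-UV circular dichroism analysis and buffer ionic-strength bookkeeping.

Spectra are carried as mean residue ellipticity (MRE,
deg cm^2 dmol^-1 residue^-1).  Families of spectra recorded across salt or
binding conditions are decomposed by exact SVD of the wavelength x condition
matrix; the per-condition loading of a component can then be fitted against
ionic strength with an extended Debye--Hückel screening law

    A(I) = s0 + c1 * sqrt(I) / (1 + c2 * sqrt(I)),

which is proportional to sqrt(I) at low ionic strength (the limiting law,
selectable via ``c2 = 0``) and saturates at high I.  Helix content is
estimated from the 222 nm ellipticity with the standard single-wavelength
anchors (coil at +640; helix at -40000 * (1 - 2.5/N), chain-length
corrected).  Protein and nucleic-acid contributions to a mixture spectrum are
separated by least-squares projection onto measured basis spectra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "CDSpectrum",
    "SVDResult",
    "DebyeHuckelFit",
    "to_mre",
    "from_mre",
    "svd_family",
    "fit_debye_huckel",
    "separate_components",
    "helix_fraction",
    "theta_helix",
    "THETA_COIL",
    "ionic_strength",
    "BUFFER_TABLE",
    "read_cd_csv",
    "write_cd_csv",
]

#: 222 nm ellipticity of a fully random coil (deg cm^2 dmol^-1 res^-1).
THETA_COIL = 640.0

_WL_MIN, _WL_MAX = 185.0, 320.0


def theta_helix(n_residues: int) -> float:
    """Chain-length-corrected 222 nm ellipticity of a 100% helix."""
    if n_residues <= 2:
        raise ValueError("n_residues must exceed 2 for the chain-length term")
    return -40000.0 * (1.0 - 2.5 / n_residues)


@dataclass
class CDSpectrum:
    """A CD spectrum in mean residue ellipticity with sample metadata.

    ``meta`` may carry ``concentration`` (molar), ``pathlength_cm``,
    ``n_residues``, ``salt`` (molar), ``ionic_strength`` (molar) and
    ``component`` ('protein' | 'dna' | 'mixture').
    """

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity arrays differ in shape")
        if len(self.wavelengths) and (
            np.any(np.diff(self.wavelengths) <= 0)
            or self.wavelengths[0] < _WL_MIN
            or self.wavelengths[-1] > _WL_MAX
        ):
            raise ValueError(
                f"wavelengths must be strictly increasing within "
                f"[{_WL_MIN}, {_WL_MAX}] nm"
            )
        if not np.all(np.isfinite(self.ellipticity)):
            raise ValueError("ellipticity must be finite at every wavelength")

    def at(self, wavelength: float) -> float:
        """Ellipticity at a wavelength, linearly interpolated."""
        if not (self.wavelengths[0] <= wavelength <= self.wavelengths[-1]):
            raise ValueError(
                f"{wavelength} nm outside spectral range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        return float(np.interp(wavelength, self.wavelengths, self.ellipticity))

    def resample(self, grid: np.ndarray) -> "CDSpectrum":
        return CDSpectrum(
            wavelengths=np.asarray(grid, float),
            ellipticity=np.interp(grid, self.wavelengths, self.ellipticity),
            meta=dict(self.meta),
        )


@dataclass
class SVDResult:
    """SVD of a wavelength x condition spectral family.

    ``components[:, k]`` is the k-th orthonormal spectral shape over
    ``wavelengths``; ``amplitudes[k, j]`` is its loading in condition j
    (singular value folded in), so ``components @ amplitudes`` reconstructs
    the input matrix exactly.  Component signs are fixed by positive
    correlation with the mean spectrum.
    """

    wavelengths: np.ndarray
    components: np.ndarray
    singular_values: np.ndarray
    amplitudes: np.ndarray

    def reconstruct(self, rank: int | None = None) -> np.ndarray:
        k = len(self.singular_values) if rank is None else rank
        return self.components[:, :k] @ self.amplitudes[:k, :]

    def n_significant(self, rtol: float = 1e-8) -> int:
        """Number of singular values above ``rtol`` times the largest."""
        if len(self.singular_values) == 0 or self.singular_values[0] == 0:
            return 0
        return int(np.sum(self.singular_values > rtol * self.singular_values[0]))


@dataclass
class DebyeHuckelFit:
    """Extended Debye--Hückel screening fit A(I) = s0 + c1*sqrt(I)/(1+c2*sqrt(I))."""

    s0: float
    c1: float
    c2: float
    rss: float
    converged: bool
    stderr: dict = field(default_factory=dict)

    def curve(self, ionic_strengths: np.ndarray) -> np.ndarray:
        return debye_huckel_curve(
            np.asarray(ionic_strengths, float), self.s0, self.c1, self.c2
        )


def debye_huckel_curve(
    ionic_strength: np.ndarray, s0: float, c1: float, c2: float
) -> np.ndarray:
    root = np.sqrt(np.asarray(ionic_strength, float))
    return s0 + c1 * root / (1.0 + c2 * root)


# ---------------------------------------------------------------------------
# MRE conversion


def to_mre(
    wavelengths: np.ndarray,
    signal_mdeg: np.ndarray,
    concentration: float,
    pathlength_cm: float,
    n_residues: int,
    meta: dict | None = None,
) -> CDSpectrum:
    """Convert a raw millidegree spectrum to mean residue ellipticity.

    MRE = mdeg / (10 * c_molar * pathlength_cm * n_residues); e.g. -10 mdeg
    at 40 uM, 1 mm path, 54 residues gives about -4630 deg cm^2/dmol/res.
    """
    for name, v in (
        ("concentration", concentration),
        ("pathlength_cm", pathlength_cm),
        ("n_residues", n_residues),
    ):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be > 0, got {v!r}")
    scale = 10.0 * concentration * pathlength_cm * n_residues
    meta = dict(meta or {})
    meta.update(
        concentration=concentration,
        pathlength_cm=pathlength_cm,
        n_residues=n_residues,
    )
    return CDSpectrum(
        wavelengths=np.asarray(wavelengths, float),
        ellipticity=np.asarray(signal_mdeg, float) / scale,
        meta=meta,
    )


def from_mre(spectrum: CDSpectrum) -> np.ndarray:
    """Inverse of :func:`to_mre`: raw millidegrees from MRE and metadata."""
    m = spectrum.meta
    scale = 10.0 * m["concentration"] * m["pathlength_cm"] * m["n_residues"]
    return spectrum.ellipticity * scale


# ---------------------------------------------------------------------------
# SVD of spectral families


def common_grid(spectra: Sequence[CDSpectrum], step: float = 1.0) -> np.ndarray:
    """Intersection wavelength grid at a fixed step (1 nm by default)."""
    lo = max(s.wavelengths[0] for s in spectra)
    hi = min(s.wavelengths[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength range")
    return np.arange(math.ceil(lo), math.floor(hi) + 0.5 * step, step)


def svd_family(spectra: Sequence[CDSpectrum]) -> SVDResult:
    """Exact SVD of a family of spectra (wavelength x condition matrix).

    Spectra on different grids are linearly resampled onto their common
    1 nm grid first.  Shapes are unit-l2-norm columns oriented to correlate
    positively with the family mean; amplitudes absorb the singular values so
    the full-rank reconstruction is exact.
    """
    if len(spectra) < 2:
        raise ValueError("need >= 2 spectra for a family decomposition")
    grid = common_grid(spectra)
    matrix = np.column_stack([s.resample(grid).ellipticity for s in spectra])
    u, sv, vt = np.linalg.svd(matrix, full_matrices=False)
    mean = matrix.mean(axis=1)
    amplitudes = sv[:, None] * vt
    for k in range(u.shape[1]):
        if np.dot(u[:, k], mean) < 0:
            u[:, k] *= -1.0
            amplitudes[k, :] *= -1.0
    return SVDResult(
        wavelengths=grid, components=u, singular_values=sv, amplitudes=amplitudes
    )


# ---------------------------------------------------------------------------
# Debye-Hückel trend fitting


def fit_debye_huckel(
    amplitudes: np.ndarray,
    ionic_strengths: np.ndarray,
    limiting_law: bool = False,
) -> DebyeHuckelFit:
    """Least-squares fit of the screening law to per-condition amplitudes.

    Requires >= 4 points spanning at least a 10-fold range in ionic strength.
    ``limiting_law=True`` pins c2 = 0, reducing to pure sqrt(I) dependence.
    The fitted curve is monotone in I (c2 >= 0 is enforced) and saturates at
    s0 + c1/c2.
    """
    amplitudes = np.asarray(amplitudes, float)
    ionic = np.asarray(ionic_strengths, float)
    if amplitudes.shape != ionic.shape or amplitudes.ndim != 1:
        raise ValueError("amplitudes and ionic_strengths must be equal-length 1-D")
    if len(ionic) < 4:
        raise ValueError("need >= 4 points for a Debye-Hückel fit")
    positive = ionic[ionic > 0]
    if len(positive) == 0 or positive.max() / positive.min() < 10.0:
        raise ValueError("ionic strengths must span at least a 10-fold range")

    span = float(amplitudes.max() - amplitudes.min())
    pars = lmfit.Parameters()
    pars.add("s0", value=float(amplitudes[np.argmin(ionic)]))
    pars.add("c1", value=span if span != 0 else 1.0)
    pars.add("c2", value=1.0, min=0.0, vary=not limiting_law)
    if limiting_law:
        pars["c2"].value = 0.0

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return amplitudes - debye_huckel_curve(
            ionic, p["s0"].value, p["c1"].value, p["c2"].value
        )

    try:
        res = lmfit.minimize(residual, pars, method="least_squares")
    except Exception:
        return DebyeHuckelFit(
            s0=math.nan, c1=math.nan, c2=math.nan, rss=math.inf, converged=False
        )
    return DebyeHuckelFit(
        s0=res.params["s0"].value,
        c1=res.params["c1"].value,
        c2=res.params["c2"].value,
        rss=float(np.sum(res.residual**2)),
        converged=bool(res.success),
        stderr={
            name: res.params[name].stderr for name in ("s0", "c1", "c2")
        },
    )


# ---------------------------------------------------------------------------
# Component separation and helix content


def separate_components(
    mixture: CDSpectrum,
    protein_basis: CDSpectrum,
    dna_basis: CDSpectrum,
    cond_threshold: float = 1e6,
) -> dict:
    """Attribute a protein+DNA mixture spectrum to its components.

    The mixture is projected by least squares (SVD pseudo-inverse) onto the
    two basis spectra; the protein-attributed spectrum is the mixture minus
    the fitted DNA contribution, so any bound-state protein features absent
    from the (free-)protein basis remain in it rather than being projected
    away.  Returns the protein-attributed spectrum, the fitted coefficients,
    the projection residual and the basis condition number (numerically
    collinear bases are flagged, not fatal).
    """
    grid = common_grid([mixture, protein_basis, dna_basis])
    mix = mixture.resample(grid).ellipticity
    basis = np.column_stack(
        [protein_basis.resample(grid).ellipticity, dna_basis.resample(grid).ellipticity]
    )
    u, sv, vt = np.linalg.svd(basis, full_matrices=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    # pseudo-inverse with a relative cutoff so a collinear basis degrades
    # gracefully instead of producing non-finite coefficients
    inv_sv = np.where(sv > 1e-12 * sv[0], 1.0 / np.where(sv > 0, sv, 1.0), 0.0)
    coeffs = vt.T @ ((u.T @ mix) * inv_sv)
    fitted = basis @ coeffs
    residual = mix - fitted
    dna_part = coeffs[1] * basis[:, 1]
    protein_attr = CDSpectrum(
        wavelengths=grid,
        ellipticity=mix - dna_part,
        meta={**mixture.meta, "component": "protein"},
    )
    return {
        "protein": protein_attr,
        "coefficients": {"protein": float(coeffs[0]), "dna": float(coeffs[1])},
        "residual": residual,
        "residual_norm": float(np.linalg.norm(residual)),
        "condition_number": cond,
        "collinear": cond > cond_threshold,
        "wavelengths": grid,
    }


def helix_fraction(spectrum: CDSpectrum, n_residues: int | None = None) -> float:
    """Fractional helix content from the 222 nm mean residue ellipticity.

    f = (theta_222 - theta_coil) / (theta_helix(N) - theta_coil), clipped to
    [0, 1] with a warning when the raw value falls outside.
    """
    if n_residues is None:
        n_residues = spectrum.meta.get("n_residues")
    if n_residues is None:
        raise ValueError("n_residues needed for the chain-length correction")
    theta = spectrum.at(222.0)
    f = (theta - THETA_COIL) / (theta_helix(int(n_residues)) - THETA_COIL)
    if not (0.0 <= f <= 1.0):
        warnings.warn(
            f"helix fraction {f:.3f} outside [0, 1]; clipping", stacklevel=2
        )
        f = min(max(f, 0.0), 1.0)
    return float(f)


# ---------------------------------------------------------------------------
# Ionic strength


#: Named buffers: acid dissociation constant of the relevant step and whether
#: the species is an acid (anionic conjugate base, Na+ counterions) or a base
#: (cationic conjugate acid, Cl- counterions).  Phosphate uses the second
#: ionisation, the relevant one near neutral pH, with the H2PO4-/HPO4^2-
#: pair carrying charges -1/-2.
BUFFER_TABLE: dict[str, dict] = {
    "phosphate": {"pka": 7.21, "kind": "acid", "z_acid": -1, "z_base": -2},
    "acetate": {"pka": 4.76, "kind": "acid", "z_acid": 0, "z_base": -1},
    "mes": {"pka": 6.27, "kind": "acid", "z_acid": 0, "z_base": -1},
    "tris": {"pka": 8.07, "kind": "base", "z_acid": +1, "z_base": 0},
}


def _buffer_species(
    name: str, concentration: float, ph: float
) -> list[tuple[str, float, int]]:
    entry = BUFFER_TABLE.get(name.lower())
    if entry is None:
        raise ValueError(
            f"unknown buffer {name!r}; known buffers: {sorted(BUFFER_TABLE)}"
        )
    # Henderson-Hasselbalch: fraction deprotonated at the stated pH.
    f_base = 1.0 / (1.0 + 10.0 ** (entry["pka"] - ph))
    species = [
        (f"{name}-acid", concentration * (1.0 - f_base), entry["z_acid"]),
        (f"{name}-base", concentration * f_base, entry["z_base"]),
    ]
    # Counterions restoring electroneutrality: Na+ for acid-type buffers
    # (added as sodium salts / NaOH-titrated), Cl- for base-type (HCl-titrated).
    net_charge = sum(c * z for _, c, z in species)
    if net_charge < 0:
        species.append(("Na+", -net_charge, +1))
    elif net_charge > 0:
        species.append(("Cl-", net_charge, -1))
    return species


def ionic_strength(
    recipe: Sequence[tuple[str, float, int]] | None = None,
    buffers: Sequence[tuple[str, float]] | None = None,
    ph: float = 7.0,
) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i^2) of a buffer recipe, molar.

    ``recipe`` lists fully dissociated species as (name, molar concentration,
    charge); 1:1 salts like NaCl or KF may be given as a single entry with
    charge 0, which is expanded into its +1/-1 ion pair.  ``buffers`` lists
    (named weak acid/base, total molar concentration) pairs, speciated by
    Henderson-Hasselbalch at ``ph`` with counterions completing
    electroneutrality.  Example: 25 mM sodium phosphate pH 6.8 with 50 mM
    NaCl gives I ~ 0.09 M (~100 mM at the nearest-100 reporting precision).
    """
    species: list[tuple[str, float, int]] = []
    for name, conc, charge in recipe or []:
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if charge == 0:
            # a neutral entry denotes a 1:1 monovalent salt (NaCl, KF, ...)
            species.append((f"{name}+", conc, +1))
            species.append((f"{name}-", conc, -1))
        else:
            species.append((name, conc, charge))
    for name, conc in buffers or []:
        if conc < 0:
            raise ValueError(f"negative concentration for buffer {name!r}")
        species.extend(_buffer_species(name, conc, ph))
    return 0.5 * sum(c * z * z for _, c, z in species)


# ---------------------------------------------------------------------------
# CSV I/O


def read_cd_csv(path, meta: dict | None = None) -> CDSpectrum:
    """Read a CD spectrum CSV with columns wavelength_nm, signal, unit
    ('mdeg' requires concentration/pathlength/residue metadata; 'MRE' is
    taken as already normalised)."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "signal", "unit"}
    if not required <= set(df.columns):
        raise ValueError(f"CD CSV must have columns {sorted(required)}")
    meta = dict(meta or {})
    units = set(df["unit"].astype(str))
    if units == {"mdeg"}:
        for key in ("concentration", "pathlength_cm", "n_residues"):
            if key not in meta:
                raise ValueError(f"mdeg spectrum needs metadata field {key!r}")
        return to_mre(
            df["wavelength_nm"].to_numpy(),
            df["signal"].to_numpy(),
            concentration=meta["concentration"],
            pathlength_cm=meta["pathlength_cm"],
            n_residues=meta["n_residues"],
            meta=meta,
        )
    if units == {"MRE"}:
        return CDSpectrum(
            wavelengths=df["wavelength_nm"].to_numpy(),
            ellipticity=df["signal"].to_numpy(),
            meta=meta,
        )
    raise ValueError(f"unit column must be uniformly 'mdeg' or 'MRE', got {units}")


def write_cd_csv(spectrum: CDSpectrum, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths,
            "signal": spectrum.ellipticity,
            "unit": "MRE",
        }
    ).to_csv(path, index=False)
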