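"""High-level analysis runners binding the pipeline stages together.

Each runner consumes a :class:`RunConfig`, executes one of the headline
analyses (CD salt series, CD binding comparison, NMR titration, synthetic
bundle generation, CSP structure mapping) and writes a machine-readable JSON
report plus a log recording the package version, a config hash and the seed.
The CLI in :mod:`specbind.cli` is a thin shell over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import specbind
from specbind.cd import (
    fit_debye_huckel,
    helix_fraction,
    ionic_strength,
    read_cd_csv,
    separate_components,
    svd_family,
    write_cd_csv,
)
from specbind.equilibrium import BindingParameters, fit_titration
from specbind.nmr import (
    map_csp_to_structure,
    read_sparky,
    secondary_shifts,
    summarize_csp,
    track_titration,
    write_sparky,
)
from specbind.synthetic import (
    GroundTruth,
    gen_cd_salt_series,
    gen_mixture_spectrum,
    gen_titration,
)

__all__ = [
    "RunConfig",
    "ValidationError",
    "run_generate",
    "run_cd_salt",
    "run_cd_binding",
    "run_nmr_titration",
    "run_map_structure",
]

logger = logging.getLogger("specbind")


class ValidationError(ValueError):
    """Input validation failure at the workbench level (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Configuration for one analysis run."""

    analysis: str  # generate | cd-salt | cd-binding | nmr-titration | map-structure
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "specbind_out"
    seed: int = 0
    # fit options
    kd_bounds: tuple[float, float] = (1e-9, 1e-1)
    kd_init: float | None = None
    probes: list[str] | str = "auto"
    dimension: str = "h"
    n_auto_probes: int = 2
    # structure mapping
    structure: str | None = None
    residue_offset: int = 0
    csp_floor: float = 0.01
    # generation
    truth: dict = field(default_factory=dict)
    ionic_strengths: list[float] = field(default_factory=list)
    # cd
    n_residues: int | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def hash(self) -> str:
        # output_dir excluded: the hash identifies the analysis, not where
        # its results land, so reruns into different directories compare equal
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "output_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_report(config: RunConfig, name: str, payload: dict) -> Path:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package_version": specbind.__version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        **payload,
    }
    path = out_dir / f"{name}.json"
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    log_path = out_dir / f"{name}.log"
    log_path.write_text(
        f"specbind {specbind.__version__}\n"
        f"analysis: {config.analysis}\n"
        f"config hash: {config.hash()}\n"
        f"seed: {config.seed}\n"
    )
    logger.info("wrote %s", path)
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return str(obj)


# ---------------------------------------------------------------------------
# generate


def run_generate(config: RunConfig) -> Path:
    """Write a synthetic data bundle (peak lists, CD series, manifest)."""
    truth = GroundTruth(**{**config.truth, "seed": config.seed})
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lists = gen_titration(truth)
    list_files = []
    for pl in lists:
        fname = f"titration_ratio_{pl.guest_ratio:.2f}.list"
        write_sparky(pl, out_dir / fname)
        list_files.append(fname)

    ionic = config.ionic_strengths or [0.001, 0.025, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7]
    spectra = gen_cd_salt_series(truth, ionic)
    cd_files = []
    for spec in spectra:
        fname = f"cd_I_{spec.meta['ionic_strength']:.3f}M.csv"
        write_cd_csv(spec, out_dir / fname)
        cd_files.append(fname)

    triple = gen_mixture_spectrum(truth)
    for label, spec in triple.items():
        write_cd_csv(spec, out_dir / f"cd_binding_{label}.csv")

    manifest = {
        "truth": truth.to_manifest(),
        "peak_lists": [
            {"file": f, "guest_ratio": pl.guest_ratio, "host_total": truth.host_total}
            for f, pl in zip(list_files, lists)
        ],
        "cd_salt_series": [
            {"file": f, "ionic_strength": i} for f, i in zip(cd_files, ionic)
        ],
        "cd_binding": {k: f"cd_binding_{k}.csv" for k in triple},
    }
    return _write_report(config, "manifest", manifest)


# ---------------------------------------------------------------------------
# cd-salt


def _load_cd_inputs(config: RunConfig):
    """Load CD spectra either from a generate-bundle manifest or from CSVs
    with ionic_strength encoded in a sidecar/manifest."""
    inputs = [Path(p) for p in config.inputs]
    spectra = []
    if len(inputs) == 1 and inputs[0].name == "manifest.json":
        manifest = json.loads(inputs[0].read_text())
        base = inputs[0].parent
        for entry in manifest["cd_salt_series"]:
            spec = read_cd_csv(base / entry["file"])
            spec.meta["ionic_strength"] = entry["ionic_strength"]
            spec.meta.setdefault(
                "n_residues", manifest["truth"].get("n_residues", config.n_residues)
            )
            spectra.append(spec)
        return spectra
    for path in inputs:
        sidecar = path.with_suffix(".yaml")
        meta = (
            yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
        ) or {}
        if config.n_residues is not None:
            meta.setdefault("n_residues", config.n_residues)
        spec = read_cd_csv(path, meta=meta)
        if "ionic_strength" not in spec.meta:
            raise ValidationError(
                f"{path}: missing 'ionic_strength' metadata (sidecar "
                f"{sidecar.name} must define it)"
            )
        spectra.append(spec)
    return spectra


def run_cd_salt(config: RunConfig) -> Path:
    """CD salt-series pipeline: MRE -> SVD -> Debye-Hückel fit -> report."""
    inputs = [Path(p) for p in config.inputs]
    if not (len(inputs) == 1 and inputs[0].name == "manifest.json"):
        if len(inputs) < 4:
            raise ValidationError(
                f"cd-salt needs >= 2 spectra for SVD and >= 4 for the "
                f"salt-trend fit; got {len(inputs)}"
            )
    spectra = _load_cd_inputs(config)
    if len(spectra) < 4:
        raise ValidationError(
            f"cd-salt needs >= 2 spectra for SVD and >= 4 for the salt-trend "
            f"fit; got {len(spectra)}"
        )
    ionic = np.array([s.meta["ionic_strength"] for s in spectra])
    order = np.argsort(ionic)
    spectra = [spectra[i] for i in order]
    ionic = ionic[order]

    svd = svd_family(spectra)
    second_amp = svd.amplitudes[1, :]
    dh_svd = fit_debye_huckel(second_amp, ionic)

    helices = []
    for s in spectra:
        n = s.meta.get("n_residues")
        if n is None:
            raise ValidationError(
                "helix estimation needs n_residues metadata per spectrum"
            )
        helices.append(helix_fraction(s, n_residues=int(n)))
    dh_helix = fit_debye_huckel(np.array(helices), ionic)

    report = {
        "n_spectra": len(spectra),
        "ionic_strengths_molar": ionic,
        "singular_values": svd.singular_values,
        "n_significant_components": svd.n_significant(rtol=1e-6),
        "second_component_amplitudes": second_amp,
        "debye_huckel_svd_amplitude": {
            "s0": dh_svd.s0, "c1": dh_svd.c1, "c2": dh_svd.c2,
            "rss": dh_svd.rss, "converged": dh_svd.converged,
        },
        "helix_fractions": helices,
        "debye_huckel_helix_fraction": {
            "s0": dh_helix.s0, "c1": dh_helix.c1, "c2": dh_helix.c2,
            "rss": dh_helix.rss, "converged": dh_helix.converged,
        },
    }
    return _write_report(config, "cd_salt_report", report)


# ---------------------------------------------------------------------------
# cd-binding


def run_cd_binding(config: RunConfig) -> Path:
    """Protein/DNA spectral separation and helix-content comparison."""
    inputs = [Path(p) for p in config.inputs]
    if len(inputs) == 1 and inputs[0].name == "manifest.json":
        manifest = json.loads(inputs[0].read_text())
        base = inputs[0].parent
        n_res = manifest["truth"].get("n_residues", 54)
        files = {k: base / v for k, v in manifest["cd_binding"].items()}
    else:
        if len(inputs) != 3:
            raise ValidationError(
                "cd-binding needs exactly 3 CSVs: protein, dna, mixture"
            )
        n_res = config.n_residues or 54
        files = dict(zip(("protein", "dna", "mixture"), inputs))
    spectra = {
        k: read_cd_csv(p, meta={"n_residues": n_res}) for k, p in files.items()
    }
    sep = separate_components(spectra["mixture"], spectra["protein"], spectra["dna"])
    free_helix = helix_fraction(spectra["protein"], n_residues=n_res)
    bound_helix = helix_fraction(sep["protein"], n_residues=n_res)
    report = {
        "helix_fraction_free": free_helix,
        "helix_fraction_bound": bound_helix,
        "separation_coefficients": sep["coefficients"],
        "residual_norm": sep["residual_norm"],
        "basis_condition_number": sep["condition_number"],
        "collinear_basis": sep["collinear"],
    }
    return _write_report(config, "cd_binding_report", report)


# ---------------------------------------------------------------------------
# nmr-titration


def _load_peaklists(config: RunConfig):
    inputs = [Path(p) for p in config.inputs]
    if len(inputs) == 1 and inputs[0].name == "manifest.json":
        manifest = json.loads(inputs[0].read_text())
        base = inputs[0].parent
        return [
            read_sparky(
                base / e["file"],
                condition={
                    "guest_ratio": e["guest_ratio"],
                    "host_total": e["host_total"],
                },
            )
            for e in manifest["peak_lists"]
        ]
    lists = []
    for path in inputs:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise ValidationError(
                f"{path}: peak list needs a {sidecar.name} sidecar with "
                "guest_ratio and host_total"
            )
        cond = yaml.safe_load(sidecar.read_text()) or {}
        for key in ("guest_ratio", "host_total"):
            if key not in cond:
                raise ValidationError(f"{sidecar}: missing field {key!r}")
        lists.append(read_sparky(path, condition=cond))
    return lists


def _auto_probes(lists, k: int) -> list[str]:
    """Largest-CSP probes between the free and final peak lists."""
    result = secondary_shifts(lists[0], lists[-1])
    ranked = sorted(result.csps, key=lambda c: (-c.combined, c.residue))
    return [c.assignment for c in ranked[:k]]


def run_nmr_titration(config: RunConfig) -> Path:
    """Track probes across a titration, fit the 1:1 model, report K_d."""
    lists = sorted(_load_peaklists(config), key=lambda pl: pl.guest_ratio)
    if len(lists) < 3:
        raise ValidationError(f"need >= 3 peak lists, got {len(lists)}")
    if config.probes == "auto":
        probes = _auto_probes(lists, config.n_auto_probes)
    else:
        probes = list(config.probes)

    from specbind.equilibrium import TitrationSeries

    series = TitrationSeries()
    per_probe: dict[str, dict] = {}
    free_assignments = set(lists[0].by_assignment())
    for probe in probes:
        if probe not in free_assignments:
            per_probe[probe] = {"status": "missing from free list"}
            continue
        probe_series, diag = track_titration(
            lists, probe, dimension=config.dimension
        )
        pts = probe_series.points.get(probe, [])
        shifts = [p.observed_shift for p in pts]
        ratios = [p.guest_total / p.host_total for p in pts]
        # plateau diagnostic: does the curve flatten at ratio >= 1?
        plateau = None
        at_or_above = [s for r, s in zip(ratios, shifts) if r >= 1.0]
        if len(at_or_above) >= 2 and max(abs(s) for s in shifts) > 0:
            span = max(abs(s) for s in shifts)
            plateau = abs(at_or_above[-1] - at_or_above[0]) < 0.05 * span
        per_probe[probe] = {
            "status": "tracked",
            "n_points": len(pts),
            "guest_ratios": ratios,
            "shifts_ppm": shifts,
            "plateau_at_saturation": plateau,
            "match_distances": diag["distance_ppm"].tolist(),
        }
        for p in pts:
            series.add(probe, p)

    tracked = [p for p, d in per_probe.items() if d.get("status") == "tracked"]
    if not tracked:
        report = {
            "status": "inconclusive",
            "per_probe": per_probe,
            "reason": "no probe could be tracked",
        }
        return _write_report(config, "nmr_titration_report", report)

    init = (
        BindingParameters(kd=config.kd_init) if config.kd_init else None
    )
    fit = fit_titration(series, init=init, bounds=tuple(config.kd_bounds))

    csp = secondary_shifts(lists[0], lists[-1])
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csp.to_tsv(out_dir / "csp_free_vs_final.tsv", floor=config.csp_floor)
    report = {
        "status": "ok" if fit.converged else "non-convergent",
        "probes": tracked,
        "fit": fit.to_dict(),
        "kd_micromolar": fit.kd * 1e6 if math.isfinite(fit.kd) else None,
        "per_probe": per_probe,
        "csp_free_vs_final": summarize_csp(csp.csps),
        "csp_missing_in_free": csp.missing_in_reference,
        "csp_missing_in_final": csp.missing_in_perturbed,
    }
    return _write_report(config, "nmr_titration_report", report)


# ---------------------------------------------------------------------------
# map-structure


def run_map_structure(config: RunConfig) -> Path:
    """Project free-vs-final CSPs onto a PDB structure (B-factor column)."""
    if config.structure is None:
        raise ValidationError("map-structure needs a PDB path in 'structure'")
    lists = sorted(_load_peaklists(config), key=lambda pl: pl.guest_ratio)
    if len(lists) < 2:
        raise ValidationError("need at least the free and one perturbed list")
    csp = secondary_shifts(lists[0], lists[-1])
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_pdb = out_dir / "csp_mapped.pdb"
    mapped = map_csp_to_structure(
        csp.csps,
        config.structure,
        out_pdb,
        floor=config.csp_floor,
        residue_offset=config.residue_offset,
    )
    report = {
        "structure": str(config.structure),
        "output_pdb": str(out_pdb),
        "residue_offset": config.residue_offset,
        "floor_ppm": config.csp_floor,
        "mapped_values": {str(k): v for k, v in sorted(mapped.items())},
    }
    return _write_report(config, "map_structure_report", report)
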