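"""HSQC peak-list handling and chemical-shift-perturbation (CSP) analysis.

Works on Sparky-style text peak lists (``Assignment  w1(15N)  w2(1H)
[Height]``).  Assignments combine a one-letter residue code, the residue
number in the full engrailed sequence (456--510 for enHD) and an atom tag:
backbone amides (``N-H``) and arginine sidechain eNH groups (``NE-HE``) are
both first-class probes, since sidechain guanidinium amides are the reporters
of choice for protein--DNA salt-bridge contacts at low pH.

The combined CSP follows the standard amide weighting

    combined = sqrt(dH^2 + (alpha * dN)^2),  alpha = 0.14 by default,

which compresses the ~5x wider 15N shift range onto the 1H scale.  Peaks are
tracked across a titration by nearest-neighbour matching in this weighted
shift space, and per-residue CSPs can be projected onto a PDB structure via
the B-factor column on a log scale.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from specbind.equilibrium import TitrationPoint, TitrationSeries

__all__ = [
    "Peak",
    "PeakList",
    "ResidueCSP",
    "CSPResult",
    "parse_assignment",
    "read_sparky",
    "write_sparky",
    "secondary_shifts",
    "summarize_csp",
    "track_titration",
    "map_csp_to_structure",
    "DEFAULT_ALPHA",
]

#: Standard 15N weighting in the combined amide CSP.
DEFAULT_ALPHA = 0.14

#: Amide detection windows (validation is a warning, not an error: folded
#: peaks and unusual environments legitimately fall outside).
_H_WINDOW = (5.0, 13.0)
_N_WINDOW = (100.0, 135.0)

_ASSIGNMENT_RE = re.compile(r"^([A-Za-z])(\d+)(\D*)$")


def parse_assignment(text: str) -> tuple[str, int, str]:
    """Split an assignment like ``R456N-H`` or ``R456NE-HE`` into
    (residue letter, residue number, atom tag).

    The atom tag is normalised: backbone amides -> ``"NH"``, arginine
    sidechain eNH -> ``"eNH"``; anything else is kept verbatim.
    """
    m = _ASSIGNMENT_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse assignment {text!r}")
    letter, number, tag = m.group(1).upper(), int(m.group(2)), m.group(3)
    tag = tag.strip("-").upper().replace("-", "")
    if tag in ("", "NH", "HN", "H", "N"):
        tag = "NH"
    elif tag in ("NEHE", "NE", "HE", "ENH"):
        tag = "eNH"
    return letter, number, tag


@dataclass(frozen=True)
class Peak:
    """A single HSQC cross-peak."""

    assignment: str
    h_shift: float
    n_shift: float
    height: float | None = None

    def __post_init__(self) -> None:
        parse_assignment(self.assignment)  # validates format
        if not (_H_WINDOW[0] <= self.h_shift <= _H_WINDOW[1]):
            warnings.warn(
                f"{self.assignment}: 1H shift {self.h_shift} ppm outside the "
                f"usual amide window {_H_WINDOW}", stacklevel=2,
            )
        if not (_N_WINDOW[0] <= self.n_shift <= _N_WINDOW[1]):
            warnings.warn(
                f"{self.assignment}: 15N shift {self.n_shift} ppm outside the "
                f"usual amide window {_N_WINDOW}", stacklevel=2,
            )

    @property
    def residue(self) -> int:
        return parse_assignment(self.assignment)[1]

    @property
    def atom_tag(self) -> str:
        return parse_assignment(self.assignment)[2]


@dataclass
class PeakList:
    """One HSQC spectrum's peaks plus the condition it was recorded at.

    ``condition`` must carry ``guest_ratio`` (guest:host molar ratio; 0 for
    the free protein) and may carry pH, salt (molar) and ``host_total``.
    """

    peaks: list[Peak]
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peaks:
            if p.assignment in seen:
                raise ValueError(f"duplicate assignment {p.assignment!r}")
            seen.add(p.assignment)

    @property
    def guest_ratio(self) -> float:
        return float(self.condition.get("guest_ratio", 0.0))

    def by_assignment(self) -> dict[str, Peak]:
        return {p.assignment: p for p in self.peaks}

    def get(self, assignment: str) -> Peak | None:
        return self.by_assignment().get(assignment)


@dataclass(frozen=True)
class ResidueCSP:
    """Per-residue secondary shifts and their combined scalar (ppm).

    ``combined = sqrt(dh^2 + (alpha*dn)^2)`` is nonnegative, zero iff both
    components are zero, and invariant under a joint sign flip of (dh, dn).
    """

    residue: int
    assignment: str
    dh: float
    dn: float
    alpha: float = DEFAULT_ALPHA

    @property
    def combined(self) -> float:
        return math.hypot(self.dh, self.alpha * self.dn)

    def log_combined(self, floor: float = 0.01) -> float:
        """log10(combined / floor), floored at 0 — the log-scale value used
        for structure mapping (floor in ppm)."""
        return math.log10(max(self.combined, floor) / floor)


@dataclass
class CSPResult:
    """Output of :func:`secondary_shifts`: shared-assignment CSPs plus the
    assignments present in only one of the two lists (never silently
    dropped — e.g. peaks broadened beyond detection in the free state)."""

    csps: list[ResidueCSP]
    missing_in_reference: list[str]
    missing_in_perturbed: list[str]

    def to_frame(self, floor: float = 0.01) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [c.residue for c in self.csps],
                "assignment": [c.assignment for c in self.csps],
                "dh_ppm": [c.dh for c in self.csps],
                "dn_ppm": [c.dn for c in self.csps],
                "combined_ppm": [c.combined for c in self.csps],
                "log_combined": [c.log_combined(floor) for c in self.csps],
            }
        )

    def to_tsv(self, path, floor: float = 0.01) -> None:
        self.to_frame(floor).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sparky-style I/O


def read_sparky(source, condition: dict | None = None) -> PeakList:
    """Read a Sparky ``.list`` peak list.

    Expected columns: ``Assignment  w1  w2  [Height]`` with w1 = 15N ppm and
    w2 = 1H ppm (the conventional axis order for an 15N-HSQC list).  A header
    line starting with 'Assignment' is skipped; blank lines ignored.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    peaks = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"malformed peak-list line: {line!r}")
        height = float(parts[3]) if len(parts) > 3 else None
        peaks.append(
            Peak(
                assignment=parts[0],
                n_shift=float(parts[1]),
                h_shift=float(parts[2]),
                height=height,
            )
        )
    return PeakList(peaks=peaks, condition=dict(condition or {}))


def read_peaks_csv(path, condition: dict | None = None) -> PeakList:
    """CSV alternative to the Sparky list: explicit headers ``assignment``,
    ``h_ppm``, ``n_ppm`` and optional ``height``."""
    df = pd.read_csv(path)
    required = {"assignment", "h_ppm", "n_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak CSV missing columns: {sorted(missing)}")
    peaks = [
        Peak(
            assignment=str(row["assignment"]),
            h_shift=float(row["h_ppm"]),
            n_shift=float(row["n_ppm"]),
            height=(
                float(row["height"])
                if "height" in df.columns and not pd.isna(row["height"])
                else None
            ),
        )
        for _, row in df.iterrows()
    ]
    return PeakList(peaks=peaks, condition=dict(condition or {}))


def write_sparky(peaklist: PeakList, path=None) -> str:
    """Serialise a :class:`PeakList` to Sparky ``.list`` text (w1 = 15N)."""
    lines = [f"{'Assignment':>12} {'w1':>10} {'w2':>10} {'Height':>12}"]
    for p in peaklist.peaks:
        h = f"{p.height:12.1f}" if p.height is not None else f"{'':>12}"
        lines.append(f"{p.assignment:>12} {p.n_shift:10.4f} {p.h_shift:10.4f} {h}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# CSP computation


def secondary_shifts(
    reference: PeakList,
    perturbed: PeakList,
    alpha: float = DEFAULT_ALPHA,
) -> CSPResult:
    """Per-assignment secondary shifts ``perturbed - reference``.

    ``dh``/``dn`` are antisymmetric under swapping the two lists; the
    combined scalar is symmetric.
    """
    ref = reference.by_assignment()
    per = perturbed.by_assignment()
    shared = sorted(set(ref) & set(per), key=lambda a: parse_assignment(a)[1:])
    if not shared:
        raise ValueError("peak lists share no assignments")
    csps = [
        ResidueCSP(
            residue=parse_assignment(a)[1],
            assignment=a,
            dh=per[a].h_shift - ref[a].h_shift,
            dn=per[a].n_shift - ref[a].n_shift,
            alpha=alpha,
        )
        for a in shared
    ]
    return CSPResult(
        csps=csps,
        missing_in_reference=sorted(set(per) - set(ref)),
        missing_in_perturbed=sorted(set(ref) - set(per)),
    )


def summarize_csp(csps: Sequence[ResidueCSP], top_k: int = 10) -> dict:
    """Mean absolute 1H/15N shifts, mean combined CSP, and the top-k probes
    by combined CSP (ties broken by residue number)."""
    csps = list(csps)
    if not csps:
        raise ValueError("no CSPs to summarise")
    ranked = sorted(csps, key=lambda c: (-c.combined, c.residue))
    return {
        "n_residues": len(csps),
        "mean_abs_dh_ppm": float(np.mean([abs(c.dh) for c in csps])),
        "mean_abs_dn_ppm": float(np.mean([abs(c.dn) for c in csps])),
        "mean_combined_ppm": float(np.mean([c.combined for c in csps])),
        "top_residues": [
            {"assignment": c.assignment, "combined_ppm": c.combined}
            for c in ranked[:top_k]
        ],
    }


# ---------------------------------------------------------------------------
# Titration tracking


def track_titration(
    lists: Sequence[PeakList],
    probe: str,
    dimension: str = "h",
    alpha: float = DEFAULT_ALPHA,
    reject_radius: float = 0.5,
    overrides: dict[float, str] | None = None,
) -> tuple[TitrationSeries, pd.DataFrame]:
    """Follow one probe through an ordered series of peak lists.

    The probe must be assigned in the first (free) list.  In each subsequent
    list the peak nearest to the previous position in the weighted shift
    metric ``sqrt(dH^2 + (alpha dN)^2)`` is taken as the probe, unless it is
    further than ``reject_radius`` ppm (combined) away, in which case the
    point is treated as lost — mirroring intermediate-exchange broadening.
    More than one consecutive lost point truncates the series with a warning.
    ``overrides`` maps guest_ratio -> assignment for manual matches.

    Returns the extracted :class:`TitrationSeries` (shifts relative to the
    free point, in ``dimension``: ``"h"``, ``"n"`` or ``"combined"``) and a
    per-point diagnostic table with the match distances.
    """
    if len(lists) < 3:
        raise ValueError("need at least 3 peak lists to track a titration")
    if dimension not in ("h", "n", "combined"):
        raise ValueError("dimension must be 'h', 'n' or 'combined'")
    lists = sorted(lists, key=lambda pl: pl.guest_ratio)
    free = lists[0]
    if free.guest_ratio != 0:
        raise ValueError("first peak list must be the free state (ratio 0)")
    start = free.get(probe)
    if start is None:
        raise ValueError(f"probe {probe!r} not assigned in the free peak list")
    overrides = overrides or {}

    series = TitrationSeries()
    diag_rows = []
    prev = start
    lost_streak = 0
    for pl in lists:
        host_total = float(pl.condition.get("host_total", math.nan))
        guest_total = host_total * pl.guest_ratio if math.isfinite(host_total) else pl.guest_ratio
        if pl.guest_ratio in overrides:
            match = pl.get(overrides[pl.guest_ratio])
            dist = 0.0 if match is None else _weighted_distance(prev, match, alpha)
        else:
            match, dist = _nearest_peak(prev, pl, alpha)
        if match is None or dist > reject_radius:
            lost_streak += 1
            diag_rows.append(
                {"guest_ratio": pl.guest_ratio, "matched": None,
                 "distance_ppm": dist, "lost": True}
            )
            if lost_streak > 1:
                warnings.warn(
                    f"probe {probe!r} lost for >1 consecutive point at ratio "
                    f"{pl.guest_ratio}; truncating series", stacklevel=2,
                )
                break
            continue
        lost_streak = 0
        dh = match.h_shift - start.h_shift
        dn = match.n_shift - start.n_shift
        if dimension == "h":
            shift = dh
        elif dimension == "n":
            shift = dn
        else:
            shift = math.hypot(dh, alpha * dn)
        series.add(
            probe,
            TitrationPoint(
                host_total=host_total if math.isfinite(host_total) else 1.0,
                guest_total=guest_total,
                observed_shift=shift,
                observed_intensity=match.height,
            ),
        )
        diag_rows.append(
            {"guest_ratio": pl.guest_ratio, "matched": match.assignment,
             "distance_ppm": dist, "lost": False}
        )
        prev = match
    return series, pd.DataFrame(diag_rows)


def _weighted_distance(a: Peak, b: Peak, alpha: float) -> float:
    return math.hypot(b.h_shift - a.h_shift, alpha * (b.n_shift - a.n_shift))


def _nearest_peak(
    ref: Peak, peaklist: PeakList, alpha: float
) -> tuple[Peak | None, float]:
    best, best_d = None, math.inf
    for p in peaklist.peaks:
        d = _weighted_distance(ref, p, alpha)
        if d < best_d:
            best, best_d = p, d
    return best, best_d


# ---------------------------------------------------------------------------
# Structure mapping


def map_csp_to_structure(
    csps: Sequence[ResidueCSP],
    structure_path,
    out_path,
    floor: float = 0.01,
    residue_offset: int = 0,
) -> dict[int, float]:
    """Project combined CSPs onto a PDB structure via the B-factor column.

    Every atom of a mapped residue gets ``log10(max(combined, floor)/floor)``
    (so combined = floor maps to 0 and each decade adds 1); unmapped residues
    get 0.  ``residue_offset`` is added to CSP residue numbers to match the
    PDB numbering (e.g. full-sequence engrailed numbering 456-510 vs a
    structure numbered 3-57).  Returns the residue -> mapped-value dict in
    PDB numbering.
    """
    from Bio.PDB import PDBIO, PDBParser

    values = {
        c.residue + residue_offset: c.log_combined(floor) for c in csps
    }
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("csp", str(structure_path))
    mapped: dict[int, float] = {}
    n_overlap = 0
    for residue in structure.get_residues():
        resnum = residue.id[1]
        value = values.get(resnum, 0.0)
        if resnum in values:
            n_overlap += 1
            mapped[resnum] = value
        for atom in residue.get_atoms():
            atom.set_bfactor(value)
    if n_overlap == 0:
        raise ValueError(
            "no residue overlap between CSP table and structure "
            f"(CSP residues {min(values)}-{max(values)} after offset "
            f"{residue_offset})"
        )
    pdb_io = PDBIO()
    pdb_io.set_structure(structure)
    pdb_io.save(str(out_path))
    return mapped
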