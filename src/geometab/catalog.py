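"""Multiplet signal catalogs for targeted ¹H-NMR quantification.

A :class:`SignalCatalog` lists, per metabolite, the chemical shift of the
resonance used for quantification and its multiplet shape: ``s`` singlet,
``d`` doublet, ``dd`` doublet of doublets, ``5m`` five-line 1:4:6:4:1
multiplet (a quintet-like pattern, e.g. the GABA β-CH₂ at ~1.907 ppm).

Two built-in catalogs cover the durum-wheat survey materials: aqueous
extracts of wheat shoots (Genzano di Lucania field) and of blooming spikes
(Matera field). Unknown singlets are labelled U1, U2, …; unassigned
polysaccharide anomeric doublets PS1–PS6 crowd the 5.38–5.44 ppm region
and must be fit jointly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CatalogEntry",
    "SignalCatalog",
    "MultipletModel",
    "wheat_shoots_catalog",
    "blooming_spikes_catalog",
    "SHAPE_CODES",
]

SHAPE_CODES = ("s", "d", "dd", "5m")

#: default ¹H-¹H scalar coupling (Hz) when a catalog does not specify one
DEFAULT_J_HZ = 7.0
#: default second coupling for dd shapes; two distinct couplings keep the
#: four components resolved (equal couplings would degenerate to 1:2:1)
DEFAULT_J2_HZ = 3.0


@dataclass(frozen=True)
class CatalogEntry:
    compound: str
    shift_ppm: float
    shape: str
    j_hz: tuple[float, ...] = ()

    def __post_init__(self):
        if self.shape not in SHAPE_CODES:
            raise ValueError(f"unknown multiplet shape {self.shape!r}; "
                             f"expected one of {SHAPE_CODES}")
        object.__setattr__(self, "j_hz", tuple(float(j) for j in self.j_hz))

    def couplings(self) -> tuple[float, ...]:
        """Couplings actually used, filling in defaults where unspecified."""
        if self.shape == "s":
            return ()
        if self.shape == "dd":
            if len(self.j_hz) >= 2:
                return self.j_hz[:2]
            if len(self.j_hz) == 1:
                return (self.j_hz[0], DEFAULT_J2_HZ)
            return (DEFAULT_J_HZ, DEFAULT_J2_HZ)
        # d and 5m need a single coupling
        return (self.j_hz[0],) if self.j_hz else (DEFAULT_J_HZ,)


# relative component intensities per shape (normalized to sum 1 at use time)
_SHAPE_WEIGHTS = {
    "s": np.array([1.0]),
    "d": np.array([1.0, 1.0]),
    "dd": np.array([1.0, 1.0, 1.0, 1.0]),
    "5m": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
}


def _component_offsets_hz(shape: str, j: tuple[float, ...]) -> np.ndarray:
    if shape == "s":
        return np.array([0.0])
    if shape == "d":
        return np.array([-j[0] / 2.0, j[0] / 2.0])
    if shape == "dd":
        j1, j2 = j[0], j[1]
        return np.array([-(j1 + j2) / 2, -(j1 - j2) / 2, (j1 - j2) / 2, (j1 + j2) / 2])
    if shape == "5m":
        return j[0] * np.arange(-2.0, 2.5, 1.0)
    raise ValueError(f"unknown shape {shape!r}")


@dataclass
class MultipletModel:
    """Parametric multiplet: tied centre, linewidth and total area.

    The multiplet is a sum of unit-area Lorentzians at fixed relative
    offsets (set by the shape and couplings) sharing one FWHM; component
    intensities are fixed at 1 (s), 1:1 (d), 1:1:1:1 (dd) and 1:4:6:4:1
    (5m) and scaled by a single total-area parameter.
    """

    compound: str
    center_ppm: float
    shape: str
    j_hz: tuple[float, ...] = ()
    fwhm_hz: float = 1.0
    area: float = 1.0

    def __post_init__(self):
        if self.shape not in SHAPE_CODES:
            raise ValueError(f"unknown multiplet shape {self.shape!r}")
        self.j_hz = tuple(float(v) for v in self.j_hz)
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be > 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    @classmethod
    def from_entry(cls, entry: CatalogEntry, fwhm_hz: float = 1.0,
                   area: float = 1.0) -> "MultipletModel":
        return cls(entry.compound, entry.shift_ppm, entry.shape,
                   entry.couplings(), fwhm_hz, area)

    @property
    def n_components(self) -> int:
        return len(_SHAPE_WEIGHTS[self.shape])

    def component_offsets_hz(self) -> np.ndarray:
        return _component_offsets_hz(self.shape, self.j_hz)

    def component_weights(self) -> np.ndarray:
        w = _SHAPE_WEIGHTS[self.shape]
        return w / w.sum()

    def span_hz(self) -> tuple[float, float]:
        off = self.component_offsets_hz()
        return float(off.min()), float(off.max())

    def profile(self, ppm: np.ndarray, freq_mhz: float) -> np.ndarray:
        """Evaluate the multiplet on a ppm axis (total area = ``area``)."""
        w_ppm = self.fwhm_hz / freq_mhz
        out = np.zeros_like(np.asarray(ppm, dtype=float))
        for off_hz, wt in zip(self.component_offsets_hz(), self.component_weights()):
            c = self.center_ppm + off_hz / freq_mhz
            out += wt * (2.0 / (np.pi * w_ppm)) / (1.0 + 4.0 * (ppm - c) ** 2 / w_ppm**2)
        return self.area * out


@dataclass
class SignalCatalog:
    """Ordered list of quantification targets (shifts strictly increasing)."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self):
        shifts = [e.shift_ppm for e in self.entries]
        if any(b <= a for a, b in zip(shifts, shifts[1:])):
            raise ValueError("catalog shifts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def compounds(self) -> list[str]:
        return [e.compound for e in self.entries]

    def models(self, fwhm_hz: float = 1.0) -> list[MultipletModel]:
        return [MultipletModel.from_entry(e, fwhm_hz=fwhm_hz) for e in self.entries]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignalCatalog":
        """Read a catalog CSV with columns compound, shift_ppm, shape[, j_hz].

        ``j_hz`` may hold one or two couplings separated by ``;``.
        """
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                j_raw = (row.get("j_hz") or "").strip()
                j = tuple(float(v) for v in j_raw.split(";") if v) if j_raw else ()
                entries.append(CatalogEntry(row["compound"].strip(),
                                            float(row["shift_ppm"]),
                                            row["shape"].strip(), j))
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["compound", "shift_ppm", "shape", "j_hz"])
            for e in self.entries:
                wr.writerow([e.compound, f"{e.shift_ppm:.4f}", e.shape,
                             ";".join(f"{j:g}" for j in e.j_hz)])


def _build(rows) -> SignalCatalog:
    return SignalCatalog([CatalogEntry(c, s, sh, j) for c, s, sh, j in rows])


def wheat_shoots_catalog() -> SignalCatalog:
    """Quantified signals of wheat-shoot aqueous extracts (Genzano field)."""
    return _build([
        ("Val", 0.9958, "d", ()),
        ("Ile", 1.0139, "d", ()),
        ("U1", 1.1119, "s", ()),
        ("U2", 1.2528, "s", ()),
        ("Thr", 1.3356, "d", ()),
        ("Ala", 1.4850, "d", ()),
        ("GABA", 1.9073, "5m", ()),
        ("acetic acid", 1.9230, "s", ()),
        ("Asn", 2.8734, "dd", (7.0, 3.0)),
        ("U5", 3.2063, "s", ()),
        ("U6", 3.2694, "s", ()),
        ("U7", 3.4551, "s", ()),
        ("b-glucose", 4.6511, "d", ()),
        ("a-glucose", 5.2388, "d", ()),
        ("PS1", 5.3860, "d", ()),
        ("PS2", 5.3944, "d", ()),
        ("PS3", 5.4064, "d", ()),
        ("PS4", 5.4100, "d", ()),
        ("sucrose", 5.4181, "d", ()),
        ("PS5", 5.4378, "d", ()),
        ("formate", 8.4586, "s", ()),
    ])


def blooming_spikes_catalog() -> SignalCatalog:
    """Quantified signals of blooming-spike aqueous extracts (Matera field)."""
    return _build([
        ("Val", 0.9946, "d", ()),
        ("Ile", 1.0132, "d", ()),
        ("U1", 1.1100, "s", ()),
        ("U2", 1.2515, "s", ()),
        ("Thr", 1.3335, "d", ()),
        ("Ala", 1.4828, "d", ()),
        ("GABA", 1.9073, "5m", ()),
        ("acetic acid", 1.9202, "s", ()),
        ("succinate", 2.4090, "s", ()),
        ("malate", 2.6770, "dd", (7.0, 3.0)),
        ("Asn", 2.8682, "dd", (7.0, 3.0)),
        ("U5", 3.2052, "s", ()),
        ("U6", 3.2683, "s", ()),
        ("b-glucose", 4.6613, "d", ()),
        ("a-glucose", 5.2373, "d", ()),
        ("PS1", 5.3840, "d", ()),
        ("PS4", 5.4094, "d", ()),
        ("sucrose", 5.4168, "d", ()),
        ("PS6", 5.4367, "d", ()),
        ("formate", 8.4584, "s", ()),
    ])
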