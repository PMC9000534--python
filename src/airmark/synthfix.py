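"""Deterministic generator of synthetic MSP peak lists for pipeline testing.

Emulates the post-deconvolution output of a 13-sample spiked-VOC experiment:
one nitrogen blank plus duplicate gas bags at 0.3/1/3/10/30/100 nL/L of a
27-compound VOC mixture, grouped L (0.3, 1), M (3, 10) and H (30, 100).  Each
sample's peak list carries the spiked compounds (area proportional to
concentration with lognormal noise), a shared library of background
contaminants, retention-time and mass jitter, and relative-intensity noise
that grows as concentration falls — so the base-peak and second/third-ion
rank swaps seen near the detection limit emerge from the noise model instead
of being hard-coded.

Deliberate contaminant behaviour built into the reference design:

* phenol appears at a fixed high area in every sample including the blank
  (a ubiquitous background compound), so the blank filter removes it from
  every group;
* pentane appears in the blank at roughly its 2 nL/L response, which removes
  it from the L and M group lists but not from H;
* propanol and 2-methoxyethanol have a detection limit of 0.5 nL/L and are
  therefore missing from the 0.3 nL/L samples (detection fraction 0.5 in L);
* limonene, 6-methyl-5-hepten-2-one and o-xylene have an inflated area CV
  (0.5) in group H, pushing them from "significant" toward "possibly
  significant" in the H comparisons;
* four compounds (tert-butanol, methyl propionate, butylethyl ether,
  3-hexanol) have an inflated CV (0.75) in group M, producing the borderline
  p-values of the M vs L comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .msp_io import ManifestEntry, PeakRecord, SampleManifest, write_msp
from .spectra import Spectrum, formula_to_mz, normalize_spectrum

__all__ = [
    "CompoundSpec",
    "FixtureDesign",
    "spike_volume",
    "generate_fixture",
    "reference_design",
    "GAS_CONSTANT",
]

GAS_CONSTANT = 8.2e-2  # L atm / (K mol)


def spike_volume(
    M: float,
    d: float,
    P: float = 1.0,
    Vgas: float = 0.2,
    R: float = GAS_CONSTANT,
    T: float = 298.0,
) -> float:
    """Liquid volume (mL) to evaporate for a target analyte gas volume.

    Ideal-gas moles in ``Vgas`` millilitres at pressure ``P`` and temperature
    ``T``, converted to liquid volume through molar mass ``M`` (g/mol) and
    density ``d`` (g/mL): ``(P * Vgas/1000 / (R * T)) * M / d``.  With the
    defaults the molar prefactor is 8.2e-6 mol.
    """
    for value, label in ((M, "M"), (d, "d"), (P, "P"), (Vgas, "Vgas"), (R, "R"), (T, "T")):
        if value <= 0:
            raise ValueError(f"{label} must be positive, got {value}")
    return (P * (Vgas / 1000.0) / (R * T)) * M / d


@dataclass(frozen=True)
class CompoundSpec:
    """One model analyte: retention time, fragment spectrum and response model."""

    name: str
    rt: float  # minutes
    fragments: tuple[tuple[str, float], ...]  # (cation formula, relative intensity)
    sensitivity: float  # area counts per nL/L
    lod: float = 0.1  # nL/L below which the compound is not detected
    cv_by_group: dict[str, float] = field(default_factory=dict)
    fixed_area: float | None = None  # background compound: same area everywhere
    blank_area: float | None = None  # extra presence in the blank at this area

    def library_spectrum(self) -> Spectrum:
        return normalize_spectrum(
            [(formula_to_mz(f), rel) for f, rel in self.fragments]
        )


@dataclass(frozen=True)
class BackgroundCompound:
    name: str
    rt: float
    ions: tuple[tuple[float, float], ...]
    base_area: float


@dataclass
class FixtureDesign:
    """The full synthetic experiment: compounds, groups, noise model, seed."""

    compounds: list[CompoundSpec]
    seed: int = 1
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    groups: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"L": (0.3, 1.0), "M": (3.0, 10.0), "H": (30.0, 100.0)}
    )
    blank_group: str = "blank"
    replicates: int = 2  # bags per concentration
    cv_default: float = 0.10
    rt_jitter: float = 0.02  # min, sd
    mz_jitter: float = 0.0003  # Da, sd
    intensity_jitter: float = 0.03  # relative-intensity sd at 1 nL/L
    n_background: int = 280
    background_presence: float = 0.9
    background_seed: int = 20220323  # background library layout, independent of noise
    background_log_sd: float = 0.5  # per-sample lognormal sd of background areas

    def sample_plan(self) -> list[tuple[str, str, float | None]]:
        """(sample_id, group, concentration) for the 13 samples, blank first."""
        plan: list[tuple[str, str, float | None]] = [("B1", self.blank_group, None)]
        for group, concs in self.groups.items():
            i = 1
            for conc in concs:
                for _ in range(self.replicates):
                    plan.append((f"{group}{i}", group, conc))
                    i += 1
        return plan

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "concentrations": list(self.concentrations),
            "groups": {g: list(c) for g, c in self.groups.items()},
            "blank_group": self.blank_group,
            "replicates": self.replicates,
            "cv_default": self.cv_default,
            "rt_jitter": self.rt_jitter,
            "mz_jitter": self.mz_jitter,
            "intensity_jitter": self.intensity_jitter,
            "n_background": self.n_background,
            "background_presence": self.background_presence,
            "background_seed": self.background_seed,
            "background_log_sd": self.background_log_sd,
            "compounds": [
                {
                    "name": c.name,
                    "rt": c.rt,
                    "fragments": [[f, rel] for f, rel in c.fragments],
                    "sensitivity": c.sensitivity,
                    "lod": c.lod,
                    "cv_by_group": dict(c.cv_by_group),
                    "fixed_area": c.fixed_area,
                    "blank_area": c.blank_area,
                }
                for c in self.compounds
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureDesign":
        compounds = [
            CompoundSpec(
                name=c["name"],
                rt=c["rt"],
                fragments=tuple((f, rel) for f, rel in c["fragments"]),
                sensitivity=c["sensitivity"],
                lod=c.get("lod", 0.1),
                cv_by_group=dict(c.get("cv_by_group", {})),
                fixed_area=c.get("fixed_area"),
                blank_area=c.get("blank_area"),
            )
            for c in data["compounds"]
        ]
        kwargs = {k: v for k, v in data.items() if k != "compounds"}
        if "concentrations" in kwargs:
            kwargs["concentrations"] = tuple(kwargs["concentrations"])
        if "groups" in kwargs:
            kwargs["groups"] = {g: tuple(c) for g, c in kwargs["groups"].items()}
        return cls(compounds=compounds, **kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "FixtureDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _trunc_normal(rng: np.random.Generator, sd: float, width: float = 3.0) -> float:
    if sd <= 0:
        return 0.0
    while True:
        x = float(rng.normal(0.0, sd))
        if abs(x) <= width * sd:
            return x


def _background_library(design: FixtureDesign) -> list[BackgroundCompound]:
    rng = np.random.default_rng(design.background_seed)
    library: list[BackgroundCompound] = []
    for i in range(design.n_background):
        rt = float(rng.uniform(1.2, 34.8))
        n_ions = int(rng.integers(3, 8))
        mzs = rng.uniform(31.0, 299.0, size=n_ions)
        rels = rng.uniform(0.05, 1.0, size=n_ions)
        rels[int(rng.integers(0, n_ions))] = 1.0
        base_area = float(10 ** (4.5 + rng.normal(0.0, 0.45)))
        library.append(
            BackgroundCompound(
                name=f"bg_{i:03d}",
                rt=rt,
                ions=tuple(zip(map(float, mzs), map(float, rels))),
                base_area=base_area,
            )
        )
    return library


def _intensity_sd(design: FixtureDesign, conc: float | None) -> float:
    """Relative-intensity noise grows as concentration falls (S/N effect)."""
    if conc is None:
        return design.intensity_jitter
    return design.intensity_jitter * (1.0 + math.sqrt(1.0 / conc))


def _perturb_spectrum(
    ions: tuple[tuple[float, float], ...],
    rng: np.random.Generator,
    mz_sd: float,
    intensity_sd: float,
) -> Spectrum:
    raw = []
    for mz, rel in ions:
        mz_obs = mz + _trunc_normal(rng, mz_sd)
        rel_obs = max(rel + float(rng.normal(0.0, intensity_sd)), 0.01)
        raw.append((mz_obs, rel_obs))
    return normalize_spectrum(raw)


def _sample_records(
    design: FixtureDesign,
    background: list[BackgroundCompound],
    sample_index: int,
    group: str,
    conc: float | None,
) -> list[PeakRecord]:
    rng = np.random.default_rng([design.seed, sample_index])
    records: list[PeakRecord] = []

    for compound in design.compounds:
        cv = compound.cv_by_group.get(group, design.cv_default)
        if compound.fixed_area is not None:
            area = compound.fixed_area * _lognormal(rng, cv)
            eff_conc = None
        elif conc is None:
            if compound.blank_area is None:
                continue
            area = compound.blank_area * _lognormal(rng, cv)
            eff_conc = compound.blank_area / compound.sensitivity
        elif conc >= compound.lod:
            area = compound.sensitivity * conc * _lognormal(rng, cv)
            eff_conc = conc
        else:
            continue
        rt = compound.rt + _trunc_normal(rng, design.rt_jitter)
        spectrum = _perturb_spectrum(
            compound.library_spectrum().ions,
            rng,
            design.mz_jitter,
            _intensity_sd(design, eff_conc),
        )
        records.append(PeakRecord(name=compound.name, rt=rt, area=area, spectrum=spectrum))

    for bg in background:
        if rng.random() >= design.background_presence:
            continue
        area = bg.base_area * float(
            np.exp(rng.normal(0.0, design.background_log_sd))
        )
        rt = bg.rt + _trunc_normal(rng, design.rt_jitter)
        spectrum = _perturb_spectrum(
            bg.ions, rng, design.mz_jitter, design.intensity_jitter
        )
        records.append(PeakRecord(name=bg.name, rt=rt, area=area, spectrum=spectrum))

    records.sort(key=lambda r: r.rt)
    return records


def generate_fixture(
    design: FixtureDesign, out_dir: str | Path, overwrite: bool = False
) -> SampleManifest:
    """Write the 13 MSP peak lists plus a manifest TSV; returns the manifest.

    Identical designs (same seed) produce byte-identical output.  Refuses to
    write into a directory that already holds a manifest unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    background = _background_library(design)
    entries: list[ManifestEntry] = []
    lines = ["file\tsample_id\tgroup"]
    for sample_index, (sample_id, group, conc) in enumerate(design.sample_plan()):
        records = _sample_records(design, background, sample_index, group, conc)
        filename = f"{sample_id}.msp"
        write_msp(records, out_dir / filename)
        lines.append(f"{filename}\t{sample_id}\t{group}")
        entries.append(ManifestEntry(path=out_dir / filename, sample_id=sample_id, group=group))
    manifest_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return SampleManifest(entries=tuple(entries), blank_group=design.blank_group)


def reference_design(seed: int = 1) -> FixtureDesign:
    """The canonical 27-compound three-group design.

    Retention times follow the model-analyte table; base peaks and prominent
    ions follow the values reported for the instrument where available
    (pentane/3,3-dimethyl-2-butanone at 41.038; methyl/ethyl acetate,
    isopropyl acetate, 2-pentanone, 6-methyl-5-hepten-2-one at 43.018;
    limonene 93.070 with a 67.054 second ion; methyl butyrate 74.036 with
    near-tied 43.054/43.018; 2-methyl-2-butanol 59.049 with a strong 73.065).
    The remaining fragment sets are plausible CHO cations chosen to be
    mutually distinguishable; twelve compounds have their base peak in
    m/z 41-45, reproducing the crowded low-mass region.
    """
    c = CompoundSpec
    compounds = [
        c("n-Pentane", 2.5, (("C3H5", 1.0), ("C3H7", 0.85), ("C4H9", 0.6),
          ("C3H6", 0.35), ("C5H11", 0.22), ("C3H4", 0.15), ("C5H12", 0.1)),
          sensitivity=12000, blank_area=24000),  # blank at ~2 nL/L response
        c("tert-Butanol", 2.8, (("C3H7O", 1.0), ("C3H5O", 0.3), ("C4H9", 0.25),
          ("C2H5O", 0.2), ("C4H7", 0.15), ("C3H3O", 0.1), ("C4H10O", 0.05)),
          sensitivity=16000, cv_by_group={"M": 0.75}),
        c("Isoprene", 3.1, (("C5H7", 1.0), ("C5H8", 0.6), ("C4H5", 0.45),
          ("C3H4", 0.3), ("C4H4", 0.2), ("C5H5", 0.15)), sensitivity=20000),
        c("MTBE", 3.1, (("C4H9O", 1.0), ("C3H7", 0.3), ("CH3O", 0.25),
          ("C4H9", 0.2), ("C2H5O", 0.1)), sensitivity=26000),
        c("Methyl acetate", 3.9, (("C2H3O", 1.0), ("CH3O", 0.3), ("C2H3O2", 0.25),
          ("C3H6O2", 0.2), ("C2H4O", 0.1)), sensitivity=15000),
        c("Hexane", 5.2, (("C3H5", 1.0), ("C4H9", 0.9), ("C3H7", 0.7),
          ("C4H7", 0.3), ("C5H11", 0.25), ("C6H13", 0.12)), sensitivity=13000),
        c("Propanol", 5.9, (("CH3O", 1.0), ("C3H6", 0.3), ("C3H7O", 0.18),
          ("C2H5O", 0.12), ("C3H8O", 0.08)), sensitivity=9000, lod=0.5),
        c("Butylethyl ether", 6.6, (("C3H7O", 1.0), ("C4H9", 0.45), ("C2H5O", 0.35),
          ("C4H9O", 0.3), ("C4H7", 0.15), ("C5H11O", 0.1)),
          sensitivity=22000, cv_by_group={"M": 0.75}),
        c("Ethyl acetate", 7.2, (("C2H3O", 1.0), ("C2H5O", 0.3), ("C2H4O", 0.18),
          ("C2H5O2", 0.12), ("C4H8O2", 0.1)), sensitivity=17000),
        c("Methyl propionate", 8.1, (("C3H5O", 1.0), ("CH3O", 0.4), ("C2H3O", 0.28),
          ("C2H3O2", 0.2), ("C4H8O2", 0.12)),
          sensitivity=14000, cv_by_group={"M": 0.75}),
        c("Benzene", 9.3, (("C6H6", 1.0), ("C6H5", 0.25), ("C4H3", 0.15),
          ("C3H3", 0.12), ("C6H4", 0.1)), sensitivity=30000),
        c("2-Methoxyethanol", 9.5, (("C2H5O", 1.0), ("CH3O", 0.7), ("C2H4O", 0.25),
          ("C2H5O2", 0.15), ("C3H8O2", 0.05)), sensitivity=8000, lod=0.5),
        c("Isopropyl acetate", 9.9, (("C2H3O", 1.0), ("C3H7", 0.8), ("C2H5O2", 0.3),
          ("C3H6", 0.25), ("C4H7O2", 0.15), ("C5H10O2", 0.05)), sensitivity=19000),
        c("2-Methyl-2-butanol", 9.9, (("C3H7O", 1.0), ("C4H9O", 0.9), ("C4H7", 0.3),
          ("C2H5O", 0.25), ("C3H5O", 0.2)), sensitivity=21000),
        c("Heptane", 10.5, (("C3H5", 1.0), ("C3H7", 0.93), ("C4H9", 0.6),
          ("C5H11", 0.35), ("C4H7", 0.3), ("C3H6", 0.28), ("C7H15", 0.1)),
          sensitivity=12500),
        c("Butanol", 11.7, (("C3H5", 1.0), ("C4H8", 0.85), ("CH3O", 0.5),
          ("C3H7", 0.3), ("C2H5O", 0.2), ("C4H9O", 0.12)), sensitivity=11000),
        c("2-Pentanone", 12.1, (("C2H3O", 1.0), ("C3H7", 0.25), ("C5H10O", 0.2),
          ("C2H4O", 0.15), ("C4H7O", 0.1)), sensitivity=18000),
        c("3,3-Dimethyl-2-butanone", 13.2, (("C3H5", 1.0), ("C4H9", 0.9),
          ("C2H3O", 0.5), ("C3H7", 0.3), ("C4H7", 0.25), ("C6H12O", 0.1)),
          sensitivity=20000),
        c("Methyl butyrate", 13.3, (("C3H6O2", 1.0), ("C3H7", 0.77), ("C2H3O", 0.76),
          ("C4H7O", 0.45), ("C2H3O2", 0.3), ("C3H5O", 0.2), ("C4H7O2", 0.15)),
          sensitivity=16500),
        c("Toluene", 15.3, (("C7H7", 1.0), ("C7H8", 0.7), ("C5H5", 0.15),
          ("C3H3", 0.1), ("C6H5", 0.08)), sensitivity=28000),
        c("2-Methyl-3-pentanol", 17.0, (("C2H5O", 1.0), ("C3H7O", 0.8),
          ("C4H9O", 0.3), ("C4H7", 0.25), ("C3H5", 0.2), ("C6H13O", 0.05)),
          sensitivity=15500),
        c("3-Hexanol", 17.7, (("C3H7O", 1.0), ("C4H9O", 0.65), ("C2H5O", 0.3),
          ("C4H7", 0.2), ("C5H11", 0.15), ("C6H13O", 0.05)),
          sensitivity=14500, cv_by_group={"M": 0.75}),
        c("5-Methyl-3-hexanol", 21.1, (("C5H11O", 1.0), ("C3H7O", 0.7),
          ("C4H7", 0.3), ("C5H9", 0.25), ("C2H5O", 0.2)), sensitivity=13500),
        c("o-Xylene", 21.9, (("C7H7", 1.0), ("C8H10", 0.55), ("C8H9", 0.2),
          ("C5H5", 0.12), ("C6H5", 0.1)), sensitivity=27000, cv_by_group={"H": 0.5}),
        c("6-Methyl-5-hepten-2-one", 27.1, (("C2H3O", 1.0), ("C5H9", 0.85),
          ("C4H7", 0.3), ("C6H11", 0.25), ("C7H11", 0.1), ("C8H14O", 0.08)),
          sensitivity=17500, cv_by_group={"H": 0.5}),
        c("Limonene", 27.6, (("C7H9", 1.0), ("C5H7", 0.93), ("C5H8", 0.55),
          ("C6H7", 0.3), ("C4H5", 0.25), ("C8H11", 0.15), ("C10H16", 0.2)),
          sensitivity=23000, cv_by_group={"H": 0.5}),
        c("Phenol", 30.7, (("C6H6O", 1.0), ("C5H6", 0.3), ("C6H5O", 0.25),
          ("C6H5", 0.2), ("C4H4", 0.15), ("C3H3", 0.1)),
          sensitivity=10000, fixed_area=4.0e5),
    ]
    return FixtureDesign(compounds=compounds, seed=seed)
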