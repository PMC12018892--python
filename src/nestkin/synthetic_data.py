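"""Synthetic nesting-population generator with ground truth.

Everything downstream (filtering, IBS kinship, parentage reconstruction,
breeding-habit summaries) is exercised against data produced here: a founder
pool in Hardy-Weinberg proportions over a post-filter MAF spectrum, Mendelian
transmission to hatchlings sampled in nests, matrilineal four-locus mtSTR
barcodes, polyandry within clutches, sperm storage across a season's
clutches, a father shared across two matrilines, 8-23 day internesting
intervals, 3-4 year remigration intervals, and philopatric nest placement on
a one-dimensional coastline with rare long-range (60-90 km) displacements.

Two scenario modes exist.  ``scenario="default"`` is a fixed structured plan
sized like the studied population - 35 nesting females, 59 males, 60 mating
events, 84 nests, 18 nests with more than five sampled hatchlings of which
exactly one third are multi-paternal - with randomness confined to
genotypes, dates, coordinates, missingness and depths, so recovery tests
have exact count targets.  ``scenario="random"`` draws the pedigree
structure itself from the configured rates and drives the distributional
property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from itertools import count as _counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_vcf
from .mtstr_typing import barcode as _barcode, parse_barcode

__all__ = [
    "DEFAULT_BARCODES",
    "SimulationConfig",
    "NestPlan",
    "ScenarioPlan",
    "NestTruth",
    "PedigreeTruth",
    "SimulatedDataset",
    "default_scenario",
    "two_family_scenario",
    "random_scenario",
    "simulate_founders",
    "simulate_pedigree",
    "simulate_nest_schedule",
    "simulate_dataset",
    "write_dataset",
]

DEFAULT_BARCODES = ("6-8-8-4", "6-8-9-4", "6-9-6-4", "8-7-7-4")

# one-dimensional coastline model: along-coast km -> WGS84 decimal degrees
_COAST_LAT0 = 31.60
_COAST_LON = 34.90
_KM_PER_DEG_LAT = 111.19


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


class IntegrityError(RuntimeError):
    """Cross-table identifier mismatch in an emitted dataset."""


@dataclass(frozen=True)
class NestPlan:
    """One clutch: which female, which season/clutch slot, which sires."""

    nest_id: str
    mother: str
    year: int
    clutch: int  # 1-based within the season
    sires: tuple[tuple[str, int], ...]  # (father id, n sampled hatchlings)


@dataclass
class ScenarioPlan:
    """Pedigree/nest structure prior to genotype and schedule simulation."""

    nests: list[NestPlan]
    barcodes: dict[str, str]  # mother -> mtSTR barcode

    @property
    def mothers(self) -> list[str]:
        return sorted({n.mother for n in self.nests})

    @property
    def fathers(self) -> list[str]:
        return sorted({f for n in self.nests for f, _ in n.sires})

    @property
    def mating_events(self) -> list[tuple[str, str]]:
        return sorted({(n.mother, f) for n in self.nests for f, _ in n.sires})

    def validate(self) -> None:
        ids = [n.nest_id for n in self.nests]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate nest ids in plan")
        for n in self.nests:
            if not n.sires or any(k < 1 for _, k in n.sires):
                raise ConfigurationError(f"nest {n.nest_id}: every sire needs >= 1 hatchling")
        missing = set(self.mothers) - set(self.barcodes)
        if missing:
            raise ConfigurationError(f"mothers without barcode: {sorted(missing)}")


@dataclass
class SimulationConfig:
    """All tunable knobs of the generator.

    Defaults mirror the studied population: a 12,795-SNP post-filter panel
    with MAF uniform on [0.05, 0.5]; 35 females and 59 males; polyandry in
    one third of clutches (the detectability-corrected estimate from
    well-sampled nests); sperm storage on; one father shared across two
    matrilines; 1-4 clutches per season, 8-23 days apart; 3-4 year
    remigration; read depth ~ N(40, 17); 5% missing calls.
    """

    n_snps: int = 12795
    maf: float | tuple[float, float] | Sequence[float] = (0.05, 0.5)
    n_mothers: int = 35
    n_fathers: int = 59
    polyandry_rate: float = 1.0 / 3.0
    sperm_storage: bool = True
    shared_father_events: int = 1
    recurrence_prob: float = 0.3
    clutches_per_season: tuple[int, int] = (1, 4)
    eggs_sampled_per_nest: tuple[int, int] = (1, 8)
    internesting_days: tuple[int, int] = (8, 23)
    remigration_years: tuple[int, int] = (3, 4)
    philopatry_sd_km: float = 5.0
    longrange_prob: float = 0.02
    longrange_km: tuple[float, float] = (60.0, 90.0)
    missing_rate: float = 0.05
    depth_mean: float = 40.0
    depth_sd: float = 17.0
    heteroplasmy_rate: float = 0.0
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    scenario: str = "default"
    plan: ScenarioPlan | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.n_mothers < 1 or self.n_fathers < 1:
            raise ConfigurationError("counts must be >= 1")
        for name in ("polyandry_rate", "recurrence_prob", "longrange_prob",
                     "missing_rate", "heteroplasmy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        self._maf_spectrum()  # validates
        for name in ("clutches_per_season", "eggs_sampled_per_nest",
                     "internesting_days", "remigration_years"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} must be an increasing range of ints >= 1")
        if self.shared_father_events > self.n_mothers // 2:
            raise ConfigurationError(
                "shared_father_events cannot exceed n_mothers / 2"
            )
        if self.scenario not in ("default", "random"):
            raise ConfigurationError("scenario must be 'default' or 'random'")
        for code in self.barcodes:
            parse_barcode(code)

    def _maf_spectrum(self):
        """Return a callable rng -> per-site frequencies, validating bounds."""
        maf = self.maf
        if isinstance(maf, (int, float)):
            maf = (float(maf), float(maf))
        if isinstance(maf, tuple) and len(maf) == 2 and all(
            isinstance(x, (int, float)) for x in maf
        ):
            lo, hi = float(maf[0]), float(maf[1])
            if not (0.0 < lo <= hi <= 0.5):
                raise ConfigurationError("MAF bounds must satisfy 0 < lo <= hi <= 0.5")
            n = self.n_snps
            return lambda rng: rng.uniform(lo, hi, size=n) if lo < hi else np.full(n, lo)
        freqs = np.asarray(list(maf), dtype=np.float64)
        if len(freqs) != self.n_snps:
            raise ConfigurationError("explicit MAF list must have n_snps entries")
        if ((freqs <= 0.0) | (freqs > 0.5)).any():
            raise ConfigurationError("explicit MAFs must be in (0, 0.5]")
        return lambda rng: freqs.copy()

    def to_yaml_dict(self) -> dict:
        d = asdict(self)
        d.pop("plan", None)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


# ---------------------------------------------------------------------------
# scenario plans
# ---------------------------------------------------------------------------


def default_scenario() -> ScenarioPlan:
    """The study-sized structured plan (see module docstring).

    Construction invariants are asserted at build time: 35 mothers, 59
    fathers, 60 mating events, 84 nests, 257 sampled hatchlings, 18 nests
    with more than five sampled hatchlings of which 6 are multi-paternal
    (10 multi-paternal nests overall).
    """
    nests: list[NestPlan] = []
    fid = _counter(1)
    nid = _counter(1)

    def new_father() -> str:
        return f"M{next(fid):02d}"

    def add(mother: str, year: int, clutch: int, sires) -> None:
        nests.append(NestPlan(f"N{next(nid):02d}", mother, year, clutch, tuple(sires)))

    # F01: four seasons, a new mate each season; first two seasons have a
    # small second clutch (sperm storage links it to the big one).
    f01_years = (2004, 2008, 2012, 2016)
    for s, year in enumerate(f01_years):
        fa = new_father()
        add("F01", year, 1, [(fa, 6)])
        if s < 2:
            add("F01", year, 2, [(fa, 1)])

    # F02: three seasons
    for s, year in enumerate((2010, 2013, 2016)):
        fa = new_father()
        add("F02", year, 1, [(fa, 6 if s < 2 else 5)])
        if s == 0:
            add("F02", year, 2, [(fa, 1)])

    # F03-F05: two well-sampled seasons, new mate the second time
    for m, (y1, y2) in zip(("F03", "F04", "F05"), ((2013, 2017), (2014, 2017), (2015, 2019))):
        fa = new_father()
        add(m, y1, 1, [(fa, 6)])
        add(m, y1, 2, [(fa, 1)])
        add(m, y2, 1, [(new_father(), 6)])

    # F06-F12: two moderately sampled seasons
    years_0612 = ((2005, 2009), (2007, 2010), (2009, 2013), (2011, 2014),
                  (2012, 2016), (2014, 2018), (2017, 2021))
    for m, (y1, y2) in zip((f"F{i:02d}" for i in range(6, 13)), years_0612):
        fa = new_father()
        add(m, y1, 1, [(fa, 4)])
        add(m, y1, 2, [(fa, 1)])
        add(m, y2, 1, [(new_father(), 4)])

    # F13-F18: single season with one large multi-paternal clutch
    for m, year in zip((f"F{i:02d}" for i in range(13, 19)),
                       (2006, 2008, 2010, 2015, 2019, 2020)):
        p1, p2 = new_father(), new_father()
        add(m, year, 1, [(p1, 4), (p2, 3)])
        add(m, year, 2, [(p1, 1)])

    # F19-F22: single season with one small multi-paternal clutch
    for m, year in zip((f"F{i:02d}" for i in range(19, 23)), (2003, 2012, 2018, 2022)):
        p1, p2 = new_father(), new_father()
        add(m, year, 1, [(p1, 2), (p2, 2)])
        add(m, year, 2, [(p1, 1)])

    # F23/F24: different matrilines sharing one father, three years apart
    shared = new_father()
    add("F23", 2018, 1, [(shared, 5)])
    add("F24", 2021, 1, [(shared, 5)])

    # F25-F35: single season, two clutches, sparsely sampled
    for m, year in zip((f"F{i:02d}" for i in range(25, 36)),
                       (2002, 2004, 2006, 2008, 2011, 2013, 2015, 2017, 2019, 2021, 2022)):
        fa = new_father()
        add(m, year, 1, [(fa, 2)])
        add(m, year, 2, [(fa, 1)])

    barcodes: dict[str, str] = {}
    for i in range(1, 19):
        barcodes[f"F{i:02d}"] = "6-8-8-4"
    barcodes["F23"] = "6-8-8-4"                      # 19 females
    for m in ("F19", "F20", "F21"):
        barcodes[m] = "6-8-9-4"                      # 3
    for m in ("F22", "F24", "F25", "F26", "F27"):
        barcodes[m] = "6-9-6-4"                      # 5
    for i in range(28, 35):
        barcodes[f"F{i:02d}"] = "8-7-7-4"            # 7
    barcodes["F35"] = "8-7-8-4"                      # 1

    plan = ScenarioPlan(nests=nests, barcodes=barcodes)
    plan.validate()
    n_hatch = sum(k for n in plan.nests for _, k in n.sires)
    big = [n for n in plan.nests if sum(k for _, k in n.sires) > 5]
    big_mp = [n for n in big if len(n.sires) > 1]
    mp = [n for n in plan.nests if len(n.sires) > 1]
    assert len(plan.nests) == 84, len(plan.nests)
    assert len(plan.mothers) == 35
    assert len(plan.fathers) == 59
    assert len(plan.mating_events) == 60
    assert n_hatch == 257, n_hatch
    assert len(big) == 18 and len(big_mp) == 6 and len(mp) == 10
    return plan


def two_family_scenario(
    n_family1: int = 11, n_family2a: int = 5, n_family2b: int = 5, year: int = 2019
) -> ScenarioPlan:
    """Two unrelated families in one season: the breeding-stock layout.

    Family 1 is a single full-sib clutch; family 2 is one clutch split
    between two sires (full-sib groups of ``n_family2a`` and ``n_family2b``
    that are maternal half-siblings).  Cross-family pairs are unrelated, so
    the two families anchor the av_min baseline.
    """
    nests = [
        NestPlan("N01", "F01", year, 1, (("M01", n_family1),)),
        NestPlan("N02", "F02", year, 1, (("M02", n_family2a), ("M03", n_family2b))),
    ]
    plan = ScenarioPlan(nests=nests, barcodes={"F01": "6-8-8-4", "F02": "6-9-6-4"})
    plan.validate()
    return plan


def random_scenario(config: SimulationConfig, rng: np.random.Generator) -> ScenarioPlan:
    """Draw a pedigree structure from the configured rates.

    Fathers are taken from a pool of ``n_fathers``; exhausting the pool is a
    configuration error.  ``shared_father_events`` pairs of mothers are
    linked afterwards by aliasing one mother's primary father to another's.
    """
    fathers = iter(f"M{i:02d}" for i in range(1, config.n_fathers + 1))

    def take_father() -> str:
        try:
            return next(fathers)
        except StopIteration:
            raise ConfigurationError(
                f"father pool exhausted (n_fathers={config.n_fathers}); "
                "increase n_fathers or lower polyandry/recurrence"
            ) from None

    nests: list[NestPlan] = []
    nid = _counter(1)
    mothers = [f"F{i:02d}" for i in range(1, config.n_mothers + 1)]
    primary_of: dict[str, str] = {}
    for mother in mothers:
        n_seasons = 2 if rng.random() < config.recurrence_prob else 1
        year = int(rng.integers(2002, 2021))
        years = [year]
        for _ in range(n_seasons - 1):
            years.append(years[-1] + int(rng.integers(config.remigration_years[0],
                                                      config.remigration_years[1] + 1)))
        for s, y in enumerate(years):
            primary = take_father()
            if s == 0:
                primary_of[mother] = primary
            secondary: str | None = None
            n_clutches = int(rng.integers(config.clutches_per_season[0],
                                          config.clutches_per_season[1] + 1))
            for c in range(1, n_clutches + 1):
                if not config.sperm_storage and c > 1:
                    primary = take_father()
                    secondary = None
                sires = [primary]
                if rng.random() < config.polyandry_rate:
                    if secondary is None:
                        secondary = take_father()
                    sires.append(secondary)
                n_eggs = int(rng.integers(config.eggs_sampled_per_nest[0],
                                          config.eggs_sampled_per_nest[1] + 1))
                if n_eggs < len(sires):
                    sires = sires[:n_eggs]
                split = [n_eggs // len(sires)] * len(sires)
                for i in range(n_eggs % len(sires)):
                    split[i] += 1
                nests.append(NestPlan(
                    f"N{next(nid):02d}", mother, y, c,
                    tuple((f, k) for f, k in zip(sires, split) if k > 0),
                ))
    # father sharing across matrilines
    if config.shared_father_events:
        chosen = rng.choice(len(mothers), size=2 * config.shared_father_events,
                            replace=False)
        for k in range(config.shared_father_events):
            a, b = mothers[chosen[2 * k]], mothers[chosen[2 * k + 1]]
            old, new = primary_of[b], primary_of[a]
            nests = [
                NestPlan(n.nest_id, n.mother, n.year, n.clutch,
                         tuple((new if f == old else f, c) for f, c in n.sires))
                if n.mother == b else n
                for n in nests
            ]
    codes = list(config.barcodes)
    barcodes = {m: codes[int(rng.integers(len(codes)))] for m in mothers}
    plan = ScenarioPlan(nests=nests, barcodes=barcodes)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class NestTruth:
    nest_id: str
    mother: str
    fathers: list[str]
    year: int
    clutch: int
    samples: list[str]
    date: date | None = None
    lat: float | None = None
    lon: float | None = None


@dataclass
class PedigreeTruth:
    """Ground-truth parentage for recovery testing.

    Invariants: every hatchling's mother equals its nest's mother (one
    female per nest), and the mating-event list is exactly the distinct
    (mother, father) pairs with sampled offspring.
    """

    hatchlings: dict[str, tuple[str, str, str]]  # sample -> (mother, father, nest)
    nests: dict[str, NestTruth]
    matriline: dict[str, str]  # mother -> barcode
    mating_events: list[tuple[str, str]]
    minor_haplotype: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, (m, f, nest) in self.hatchlings.items():
            if self.nests[nest].mother != m:
                raise IntegrityError(f"hatchling {s}: mother differs from nest mother")
        pairs = {(m, f) for m, f, _ in self.hatchlings.values()}
        if pairs != set(self.mating_events):
            raise IntegrityError("mating-event list inconsistent with hatchling parentage")

    @property
    def n_mothers(self) -> int:
        return len({m for m, _, _ in self.hatchlings.values()})

    @property
    def n_fathers(self) -> int:
        return len({f for _, f, _ in self.hatchlings.values()})

    @property
    def n_mating_events(self) -> int:
        return len(self.mating_events)

    @property
    def multiple_paternity_nests(self) -> list[str]:
        return sorted(n.nest_id for n in self.nests.values() if len(n.fathers) > 1)

    def sample_barcode(self, sample: str) -> str:
        return self.matriline[self.hatchlings[sample][0]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "hatchlings": {s: list(v) for s, v in self.hatchlings.items()},
            "nests": {
                k: {
                    "nest_id": n.nest_id, "mother": n.mother, "fathers": n.fathers,
                    "year": n.year, "clutch": n.clutch, "samples": n.samples,
                    "date": None if n.date is None else n.date.isoformat(),
                    "lat": n.lat, "lon": n.lon,
                }
                for k, n in self.nests.items()
            },
            "matriline": self.matriline,
            "minor_haplotype": self.minor_haplotype,
            "mating_events": [list(e) for e in self.mating_events],
            "counts": {
                "n_mothers": self.n_mothers,
                "n_fathers": self.n_fathers,
                "n_mating_events": self.n_mating_events,
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PedigreeTruth":
        payload = json.loads(Path(path).read_text())
        nests = {
            k: NestTruth(
                nest_id=d["nest_id"], mother=d["mother"], fathers=list(d["fathers"]),
                year=d["year"], clutch=d["clutch"], samples=list(d["samples"]),
                date=None if d["date"] is None else date.fromisoformat(d["date"]),
                lat=d["lat"], lon=d["lon"],
            )
            for k, d in payload["nests"].items()
        }
        return cls(
            hatchlings={s: tuple(v) for s, v in payload["hatchlings"].items()},
            nests=nests,
            matriline=payload["matriline"],
            mating_events=[tuple(e) for e in payload["mating_events"]],
            minor_haplotype=payload.get("minor_haplotype", {}),
        )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_founders(
    config: SimulationConfig,
    n_founders: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unrelated founders drawn from Hardy-Weinberg proportions.

    Returns ``(genotypes, freqs)``: an ``n_founders x n_snps`` dosage matrix
    and the per-site alternate-allele frequencies used to draw it (recorded
    so analytic oracles can condition on the true spectrum).
    """
    rng = rng or np.random.default_rng(config.seed)
    if n_founders is None:
        n_founders = config.n_mothers + config.n_fathers
    if n_founders < 1:
        raise ConfigurationError("n_founders must be >= 1")
    freqs = config._maf_spectrum()(rng)
    genotypes = rng.binomial(2, freqs, size=(n_founders, config.n_snps)).astype(np.int8)
    return genotypes, freqs


def _resolve_plan(config: SimulationConfig, rng: np.random.Generator) -> ScenarioPlan:
    if config.plan is not None:
        config.plan.validate()
        return config.plan
    if config.scenario == "default":
        return default_scenario()
    return random_scenario(config, rng)


def _mendelian_children(
    mother_g: np.ndarray, father_g: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k offspring dosages: one allele from each parent, independently per site."""
    s = mother_g.shape[0]
    maternal = rng.random((k, s)) < mother_g / 2.0
    paternal = rng.random((k, s)) < father_g / 2.0
    return (maternal.astype(np.int8) + paternal.astype(np.int8))


def simulate_pedigree(
    config: SimulationConfig,
    founders: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    plan: ScenarioPlan | None = None,
) -> tuple[PedigreeTruth, GenotypeMatrix]:
    """Simulate hatchling genotypes for a scenario plan.

    Parents are assigned rows of ``founders`` (mothers first, then fathers,
    both in sorted id order) or drawn fresh from HWE.  Hatchlings are
    Mendelian draws; missingness and read depths are applied afterwards.
    """
    rng = rng or np.random.default_rng(config.seed)
    plan = plan or _resolve_plan(config, rng)
    mothers, fathers = plan.mothers, plan.fathers
    if founders is None:
        founders = simulate_founders(config, n_founders=len(mothers) + len(fathers), rng=rng)
    geno, freqs = founders
    if geno.shape[0] < len(mothers) + len(fathers):
        raise ConfigurationError(
            f"{geno.shape[0]} founders cannot cover {len(mothers)} mothers + "
            f"{len(fathers)} fathers"
        )
    parent_g = {}
    for i, m in enumerate(mothers):
        parent_g[m] = geno[i]
    for j, f in enumerate(fathers):
        parent_g[f] = geno[len(mothers) + j]

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    hatchlings: dict[str, tuple[str, str, str]] = {}
    nest_truth: dict[str, NestTruth] = {}
    for nest in plan.nests:
        members: list[str] = []
        for father, k in nest.sires:
            kids = _mendelian_children(parent_g[nest.mother], parent_g[father], k, rng)
            for row in kids:
                sid = f"{nest.nest_id}h{len(members) + 1:02d}"
                members.append(sid)
                sample_ids.append(sid)
                rows.append(row)
                hatchlings[sid] = (nest.mother, father, nest.nest_id)
        nest_truth[nest.nest_id] = NestTruth(
            nest_id=nest.nest_id, mother=nest.mother,
            fathers=[f for f, _ in nest.sires], year=nest.year,
            clutch=nest.clutch, samples=members,
        )
    genotypes = np.stack(rows).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING
    depths = np.clip(
        np.rint(rng.normal(config.depth_mean, config.depth_sd, size=genotypes.shape)),
        0, None,
    ).astype(np.int64)
    depths[genotypes == MISSING] = 0

    minor: dict[str, str | None] = {}
    for m in mothers:
        if rng.random() < config.heteroplasmy_rate:
            counts = list(parse_barcode(plan.barcodes[m]))
            locus = int(rng.integers(len(counts)))
            counts[locus] += 1
            minor[m] = _barcode(counts)
        else:
            minor[m] = None

    truth = PedigreeTruth(
        hatchlings=hatchlings,
        nests=nest_truth,
        matriline=dict(plan.barcodes),
        mating_events=plan.mating_events,
        minor_haplotype=minor,
    )
    sites = [("1", 1000 * (j + 1), "A", "G") for j in range(config.n_snps)]
    gm = GenotypeMatrix(samples=sample_ids, sites=sites, genotypes=genotypes, depths=depths)
    return truth, gm


def simulate_nest_schedule(
    config: SimulationConfig,
    truth: PedigreeTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign calendar dates and coordinates to every nest in the truth.

    Within a season, clutch dates are separated by integer draws from
    ``internesting_days``; seasons use the plan's years (remigration gaps are
    structural).  Each female has a home position on the coastline; every
    nest is displaced by a Gaussian of scale ``philopatry_sd_km``, replaced
    with probability ``longrange_prob`` by a 60-90 km displacement.
    Mutates ``truth`` in place and returns a nest-level frame.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    by_mother: dict[str, list[NestTruth]] = {}
    for nest in truth.nests.values():
        by_mother.setdefault(nest.mother, []).append(nest)
    records = []
    coast_length = 150.0  # km of surveyed shoreline
    for mother in sorted(by_mother):
        home = float(rng.uniform(0.0, coast_length))
        base_offset = int(rng.integers(0, 31))  # nesting onset within June
        nests = sorted(by_mother[mother], key=lambda n: (n.year, n.clutch))
        season_start: dict[int, date] = {}
        last_date: dict[int, date] = {}
        for nest in nests:
            if nest.year not in season_start:
                jitter = int(rng.integers(-5, 6))
                start = date(nest.year, 6, 1) + timedelta(days=base_offset + jitter)
                season_start[nest.year] = start
                nest_date = start
            else:
                gap = int(rng.integers(config.internesting_days[0],
                                       config.internesting_days[1] + 1))
                nest_date = last_date[nest.year] + timedelta(days=gap)
            last_date[nest.year] = nest_date
            if rng.random() < config.longrange_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                pos = home + sign * float(rng.uniform(*config.longrange_km))
            else:
                pos = home + float(rng.normal(0.0, config.philopatry_sd_km))
            nest.date = nest_date
            nest.lat = round(_COAST_LAT0 + pos / _KM_PER_DEG_LAT, 6)
            nest.lon = _COAST_LON
            records.append({
                "nest_id": nest.nest_id, "mother": mother, "date": nest_date,
                "lat": nest.lat, "lon": nest.lon, "year": nest.year,
                "clutch": nest.clutch,
            })
    return pd.DataFrame(records).sort_values("nest_id").reset_index(drop=True)


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    truth: PedigreeTruth
    genotypes: GenotypeMatrix
    freqs: np.ndarray
    schedule: pd.DataFrame

    @property
    def haplotypes(self) -> dict[str, str]:
        return {s: self.truth.sample_barcode(s) for s in self.genotypes.samples}

    @property
    def nest_of(self) -> dict[str, str]:
        return {s: v[2] for s, v in self.truth.hatchlings.items()}

    def nests_frame(self) -> pd.DataFrame:
        """Long-format nest metadata (one row per sampled hatchling)."""
        rows = []
        for nest in sorted(self.truth.nests.values(), key=lambda n: n.nest_id):
            for s in nest.samples:
                rows.append({
                    "nest_id": nest.nest_id,
                    "sample_id": s,
                    "date": None if nest.date is None else nest.date.isoformat(),
                    "lat": nest.lat,
                    "lon": nest.lon,
                    "mt_haplotype": self.truth.matriline[nest.mother],
                })
        return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One seeded end-to-end draw: pedigree, genotypes, schedule, haplotypes."""
    rng = np.random.default_rng(config.seed)
    plan = _resolve_plan(config, rng)
    founders = simulate_founders(
        config, n_founders=len(plan.mothers) + len(plan.fathers), rng=rng
    )
    truth, gm = simulate_pedigree(config, founders=founders, rng=rng, plan=plan)
    schedule = simulate_nest_schedule(config, truth, rng=rng)
    return SimulatedDataset(
        config=config, truth=truth, genotypes=gm, freqs=founders[1], schedule=schedule
    )


def write_dataset(
    truth: PedigreeTruth,
    genotypes: GenotypeMatrix,
    outdir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Emit VCF, nests CSV, haplotype CSV, truth JSON (and a config echo).

    All tables are cross-checked for identifier consistency before writing;
    the output is re-readable by :mod:`nestkin.genotype_io` without loss.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nest_samples = {s for n in truth.nests.values() for s in n.samples}
    if nest_samples != set(genotypes.samples) or set(truth.hatchlings) != nest_samples:
        raise IntegrityError("sample ids differ between genotypes, nests and truth")

    paths: dict[str, Path] = {}
    paths["vcf"] = write_vcf(genotypes, outdir / "genotypes.vcf")

    nest_rows = []
    hap_rows = []
    for nest in sorted(truth.nests.values(), key=lambda n: n.nest_id):
        code = truth.matriline[nest.mother]
        minor = truth.minor_haplotype.get(nest.mother)
        for s in nest.samples:
            nest_rows.append({
                "nest_id": nest.nest_id, "sample_id": s,
                "date": None if nest.date is None else nest.date.isoformat(),
                "lat": nest.lat, "lon": nest.lon, "mt_haplotype": code,
            })
            hap_rows.append({
                "sample_id": s, "barcode": code,
                "heteroplasmic": minor is not None,
                "minor_barcode": minor if minor is not None else "",
            })
    paths["nests"] = outdir / "nests.csv"
    pd.DataFrame(nest_rows).to_csv(paths["nests"], index=False)
    paths["haplotypes"] = outdir / "haplotypes.csv"
    pd.DataFrame(hap_rows).to_csv(paths["haplotypes"], index=False)
    paths["truth"] = truth.to_json(outdir / "truth.json")
    if config is not None:
        paths["config"] = outdir / "config.yaml"
        paths["config"].write_text(yaml.safe_dump(config.to_yaml_dict(), sort_keys=True))
    return paths
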