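"""Synthetic inputs for every stage of the pipeline.

Real Arabian-leopard genotypes and detection records are not publicly
deposited, so this module fabricates datasets with the same *structure*:

* an allele-frequency specification for 8 microsatellite loci carrying 27
  alleles partitioned between the wild Omani population and the captive
  population (including captive founders wild-sourced from Yemen),
* replicate noninvasive (scat) genotypes per individual with allelic dropout,
  missing data and a sex locus, and
* spatially explicit capture histories generated from known density and
  half-normal detection parameters, for estimator-recovery testing.

Every generator is deterministic for a fixed seed and the generating truth is
carried along in the outputs so downstream estimates can be checked against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .secr import CaptureData, make_mask

__all__ = [
    "AlleleSpec",
    "GenotypeDataset",
    "SpatialScenario",
    "gen_allele_spec",
    "canonical_allele_spec",
    "canonical_partition_counts",
    "gen_genotype_dataset",
    "gen_spatial_captures",
    "realized_dropout",
]

PARTITIONS = ("wild_oman", "captive_oman", "captive_yemen")
WILD_REGIONS = ("Jabal Samhan", "Jabal Qara", "Jabal Qamar", "Nejd")
MEMBERSHIPS = ("shared", "wild_only", "captive_only", "yemen_only")

#: canonical locus panel: seven loci polymorphic in the wild plus one locus
#: polymorphic only in captivity (the eighth label is a synthetic stand-in for
#: the unnamed captive-only-polymorphic marker).
CANONICAL_LOCI = ("FCA90", "FCA105", "FCA126", "FCA279",
                  "6HDZ89", "6HDZ635", "6HDZ700", "FCA441")


def canonical_partition_counts() -> dict[str, dict[str, int]]:
    """Per-locus allele counts by membership class for the canonical panel.

    The published totals pin down only the marginal partition (27 alleles in
    total: 17 shared, 8 captive-only of which 2 Yemen-only, 2 wild-only, with
    2-5 alleles per locus and the eighth locus monomorphic in the wild).  The
    allocation of those alleles to individual loci is this package's own
    deterministic choice subject to the constraints.
    """
    return {
        "FCA90":   {"shared": 3, "wild_only": 0, "captive_only": 1, "yemen_only": 1},
        "FCA105":  {"shared": 3, "wild_only": 0, "captive_only": 1, "yemen_only": 0},
        "FCA126":  {"shared": 2, "wild_only": 1, "captive_only": 1, "yemen_only": 0},
        "FCA279":  {"shared": 2, "wild_only": 1, "captive_only": 1, "yemen_only": 0},
        "6HDZ89":  {"shared": 2, "wild_only": 0, "captive_only": 0, "yemen_only": 0},
        "6HDZ635": {"shared": 2, "wild_only": 0, "captive_only": 1, "yemen_only": 0},
        "6HDZ700": {"shared": 2, "wild_only": 0, "captive_only": 0, "yemen_only": 0},
        "FCA441":  {"shared": 1, "wild_only": 0, "captive_only": 1, "yemen_only": 1},
    }


@dataclass
class AlleleSpec:
    """Per-locus allele labels, membership classes and partition frequencies.

    ``freqs[partition][locus]`` maps allele label -> frequency; each locus's
    frequencies within a partition sum to one.  Membership classes determine
    which partitions carry an allele: shared alleles occur in all partitions,
    ``wild_only`` only in ``wild_oman``, ``captive_only`` in both captive
    partitions, ``yemen_only`` only in ``captive_yemen``.
    """

    loci: tuple[str, ...]
    alleles: dict[str, list[str]]                  # locus -> allele labels
    membership: dict[str, dict[str, str]]          # locus -> allele -> class
    freqs: dict[str, dict[str, dict[str, float]]]  # partition -> locus -> allele -> freq

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -----------------------------------------------------------
    def support(self, partition: str) -> dict[str, list[str]]:
        """Alleles with nonzero frequency in ``partition``, per locus."""
        out = {}
        for locus in self.loci:
            out[locus] = [a for a, f in self.freqs[partition][locus].items() if f > 0]
        return out

    def support_size(self, partition: str) -> int:
        return sum(len(v) for v in self.support(partition).values())

    @property
    def n_alleles_total(self) -> int:
        return sum(len(v) for v in self.alleles.values())

    def count_membership(self, cls: str) -> int:
        return sum(
            1 for locus in self.loci for a in self.alleles[locus]
            if self.membership[locus][a] == cls
        )

    def validate(self) -> None:
        for locus in self.loci:
            k = len(self.alleles[locus])
            if not 1 <= k <= 5:
                raise ValueError(f"{locus}: {k} alleles outside [1, 5]")
            for part in PARTITIONS:
                tot = sum(self.freqs[part][locus].values())
                if self.freqs[part][locus] and abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"{locus}/{part}: frequencies sum to {tot}")

    # -- serialization (canonical spec ships as a versioned JSON fixture) --
    def to_json(self) -> str:
        return json.dumps(
            {"loci": list(self.loci), "alleles": self.alleles,
             "membership": self.membership, "freqs": self.freqs},
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "AlleleSpec":
        d = json.loads(text)
        return cls(loci=tuple(d["loci"]), alleles=d["alleles"],
                   membership=d["membership"], freqs=d["freqs"])


def _partitions_for(cls: str) -> tuple[str, ...]:
    return {
        "shared": PARTITIONS,
        "wild_only": ("wild_oman",),
        "captive_only": ("captive_oman", "captive_yemen"),
        "yemen_only": ("captive_yemen",),
    }[cls]


def gen_allele_spec(
    seed: int,
    partition_counts: dict[str, dict[str, int]] | None = None,
    loci: tuple[str, ...] | None = None,
    dirichlet_alpha: float = 1.5,
) -> AlleleSpec:
    """Draw an :class:`AlleleSpec` with the given membership partition.

    Allele labels are fragment sizes on a tetranucleotide ladder.  Frequencies
    are drawn independently per partition from a symmetric Dirichlet over that
    partition's support and renormalized, so shared alleles differ in frequency
    between partitions (which is what gives the partitions F_ST > 0).
    """
    counts = partition_counts if partition_counts is not None else canonical_partition_counts()
    if loci is None:
        loci = tuple(counts.keys())
    rng = np.random.default_rng(seed)

    alleles: dict[str, list[str]] = {}
    membership: dict[str, dict[str, str]] = {}
    for li, locus in enumerate(loci):
        c = counts[locus]
        k = sum(c.get(m, 0) for m in MEMBERSHIPS)
        if k > 5:
            raise ValueError(f"{locus}: {k} alleles forced onto one locus (max 5)")
        if k < 1:
            raise ValueError(f"{locus}: needs at least one allele")
        labels = [str(96 + 10 * li + 4 * j) for j in range(k)]
        classes = [m for m in MEMBERSHIPS for _ in range(c.get(m, 0))]
        order = rng.permutation(k)
        alleles[locus] = labels
        membership[locus] = {labels[i]: classes[order[i]] for i in range(k)}

    freqs: dict[str, dict[str, dict[str, float]]] = {p: {} for p in PARTITIONS}
    for part in PARTITIONS:
        for locus in loci:
            sup = [a for a in alleles[locus] if part in _partitions_for(membership[locus][a])]
            f = {a: 0.0 for a in alleles[locus]}
            if sup:
                draw = rng.dirichlet(np.full(len(sup), dirichlet_alpha))
                draw = draw / draw.sum()
                for a, v in zip(sup, draw):
                    f[a] = float(v)
            freqs[part][locus] = f
    return AlleleSpec(loci=loci, alleles=alleles, membership=membership, freqs=freqs)


def canonical_allele_spec() -> AlleleSpec:
    """The versioned canonical spec (27 alleles; wild support 19, captive 25)."""
    text = resources.files("nimrescue").joinpath("data/canonical_allele_spec.json").read_text()
    return AlleleSpec.from_json(text)


# ---------------------------------------------------------------------------
# genotype datasets
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Replicate multilocus genotypes with individual/region/date metadata.

    ``long`` is the long-form table (one row per sample x locus) with columns
    ``sample_id, individual_id, region, period, x_km, y_km, locus, allele1,
    allele2, sex_call``; missing calls are empty strings.  ``truth`` maps
    individual_id -> {locus: (a1, a2)} with the error-free genotypes.
    """

    long: pd.DataFrame
    loci: tuple[str, ...]
    truth: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    spec: AlleleSpec | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.long["sample_id"].unique())

    def sample_table(self) -> pd.DataFrame:
        """One row per sample (metadata only)."""
        cols = ["sample_id", "individual_id", "region", "period", "x_km", "y_km", "sex_call"]
        return self.long[cols].drop_duplicates("sample_id").reset_index(drop=True)

    def genotypes_wide(self) -> dict[str, dict[str, tuple[str, str]]]:
        """sample_id -> {locus: (a1, a2)}; missing loci absent."""
        out: dict[str, dict[str, tuple[str, str]]] = {}
        for row in self.long.itertuples(index=False):
            if row.allele1 and row.allele2:
                out.setdefault(row.sample_id, {})[row.locus] = (row.allele1, row.allele2)
            else:
                out.setdefault(row.sample_id, {})
        return out

    # -- CSV ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeDataset":
        df = pd.read_csv(path, dtype=str).fillna("")
        df["x_km"] = df["x_km"].astype(float)
        df["y_km"] = df["y_km"].astype(float)
        loci = tuple(dict.fromkeys(df["locus"]))
        return cls(long=df, loci=loci)

    # -- Genepop -----------------------------------------------------------
    def to_genepop(self, path: str | Path, group_by: str = "region") -> None:
        """Write a Genepop file with 3-digit allele codes, one Pop per group."""
        codes = {
            locus: {a: f"{i + 1:03d}" for i, a in enumerate(sorted(set(self.long.loc[self.long["locus"] == locus, ["allele1", "allele2"]].to_numpy().ravel()) - {""}))}
            for locus in self.loci
        }
        wide = self.genotypes_wide()
        meta = self.sample_table()
        lines = ["Synthetic leopard microsatellite genotypes"]
        lines += list(self.loci)
        for _, grp in meta.groupby(group_by, sort=False):
            lines.append("Pop")
            for _, s in grp.iterrows():
                g = wide.get(s["sample_id"], {})
                fields = []
                for locus in self.loci:
                    if locus in g:
                        a1, a2 = g[locus]
                        fields.append(codes[locus][a1] + codes[locus][a2])
                    else:
                        fields.append("000000")
                lines.append(f"{s['sample_id']} ,  " + " ".join(fields))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_genepop(cls, path: str | Path) -> "GenotypeDataset":
        """Read a Genepop file written by :meth:`to_genepop` (3-digit codes).

        Allele labels become the numeric codes; metadata beyond the Pop
        grouping is not recoverable from Genepop and is filled with defaults.
        """
        lines = Path(path).read_text().splitlines()
        loci: list[str] = []
        i = 1
        while i < len(lines) and lines[i].strip().lower() != "pop":
            loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
            i += 1
        rows = []
        pop = -1
        for line in lines[i:]:
            if line.strip().lower() == "pop":
                pop += 1
                continue
            if "," not in line:
                continue
            name, geno = line.split(",", 1)
            name = name.strip()
            fields = geno.split()
            for locus, f in zip(loci, fields):
                a1, a2 = f[:3], f[3:]
                if a1 == "000" or a2 == "000":
                    a1 = a2 = ""
                rows.append(
                    {"sample_id": name, "individual_id": name, "region": f"pop{pop}",
                     "period": "", "x_km": 0.0, "y_km": 0.0, "locus": locus,
                     "allele1": a1.lstrip("0") or a1, "allele2": a2.lstrip("0") or a2,
                     "sex_call": ""}
                )
        return cls(long=pd.DataFrame(rows), loci=tuple(loci))


#: planar km centers of the four wild sampling regions, spanning ~250 km
_REGION_CENTERS = {
    "Jabal Samhan": (220.0, 40.0),
    "Jabal Qara": (120.0, 50.0),
    "Jabal Qamar": (30.0, 55.0),
    "Nejd": (120.0, 90.0),
    "captive_oman": (0.0, 0.0),
    "captive_yemen": (0.0, 0.0),
}


def _partition_of_region(region: str) -> str:
    if region in WILD_REGIONS:
        return "wild_oman"
    if region in ("captive_oman", "captive_yemen"):
        return region
    raise ValueError(f"unknown region {region!r}")


def gen_genotype_dataset(
    spec: AlleleSpec,
    n_individuals: dict[str, int],
    replicates: float | dict[str, int] = 3.0,
    dropout_rate: float = 0.048,
    missing_rate: float = 0.0,
    seed: int = 0,
    male_fraction: float = 0.5,
    period: str = "2017",
    region_scatter_km: float = 12.0,
) -> GenotypeDataset:
    """Generate replicate noninvasive genotypes from an allele spec.

    True genotypes are drawn under Hardy-Weinberg from the partition
    frequencies of each individual's region.  Each replicate then suffers
    per-allele dropout with probability ``dropout_rate`` (a heterozygote with
    one dropped allele is scored as a false homozygote; both dropped -> locus
    missing) and whole-locus missingness with probability ``missing_rate``.
    ``replicates`` is a Poisson mean (min 1) or an explicit per-region count.
    """
    if not n_individuals:
        raise ValueError("empty region list")
    if not (0 <= dropout_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, dict[str, tuple[str, str]]] = {}
    ind_counter = 0
    for region, n_ind in n_individuals.items():
        part = _partition_of_region(region)
        cx, cy = _REGION_CENTERS.get(region, (0.0, 0.0))
        for _ in range(n_ind):
            ind_counter += 1
            ind_id = f"ind{ind_counter:03d}"
            sex = "M" if rng.random() < male_fraction else "F"
            x = cx + rng.normal(0, region_scatter_km)
            y = cy + rng.normal(0, region_scatter_km)
            geno = {}
            for locus in spec.loci:
                f = spec.freqs[part][locus]
                labels = [a for a, p in f.items() if p > 0]
                p = np.array([f[a] for a in labels])
                a1, a2 = rng.choice(labels, size=2, p=p / p.sum())
                geno[locus] = (min(a1, a2), max(a1, a2))
            truth[ind_id] = geno
            if isinstance(replicates, dict):
                n_rep = replicates[region]
            else:
                n_rep = 1 + rng.poisson(max(replicates - 1.0, 0.0))
            for r in range(n_rep):
                sid = f"{ind_id}_s{r + 1}"
                for locus in spec.loci:
                    a1, a2 = geno[locus]
                    if rng.random() < missing_rate:
                        a1 = a2 = ""
                    elif a1 != a2:
                        d1 = rng.random() < dropout_rate
                        d2 = rng.random() < dropout_rate
                        if d1 and d2:
                            a1 = a2 = ""
                        elif d1:
                            a1 = a2
                        elif d2:
                            a2 = a1
                    rows.append(
                        {"sample_id": sid, "individual_id": ind_id, "region": region,
                         "period": period, "x_km": round(x, 3), "y_km": round(y, 3),
                         "locus": locus, "allele1": a1, "allele2": a2, "sex_call": sex}
                    )
    return GenotypeDataset(long=pd.DataFrame(rows), loci=spec.loci, truth=truth, spec=spec)


def realized_dropout(ds: GenotypeDataset) -> float:
    """Fraction of allele copies lost at truly heterozygous replicate loci."""
    dropped = total = 0
    for row in ds.long.itertuples(index=False):
        t1, t2 = ds.truth[row.individual_id][row.locus]
        if t1 == t2:
            continue
        total += 2
        if not row.allele1:          # whole locus lost: both alleles dropped
            dropped += 2
        elif row.allele1 == row.allele2:
            dropped += 1
    return dropped / total if total else float("nan")


# ---------------------------------------------------------------------------
# spatial capture histories
# ---------------------------------------------------------------------------

@dataclass
class SpatialScenario:
    """Known-truth generating model for spatial capture histories.

    ``density_per_100km2`` is the activity-center intensity; ``g0`` and
    ``sigma_km`` are half-normal detection parameters (optionally sex-specific
    via ``g0_by_sex`` / ``sigma_by_sex`` mappings with keys 'M'/'F').
    """

    detectors: pd.DataFrame            # detector_id, x_km, y_km, kind
    n_occasions: int
    density_per_100km2: float
    g0: float
    sigma_km: float
    buffer_km: float | None = None     # default 4 * sigma
    mask_spacing_km: float = 2.0
    female_fraction: float = 0.5
    g0_by_sex: dict[str, float] | None = None
    sigma_by_sex: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma_km <= 0 or self.density_per_100km2 <= 0:
            raise ValueError("sigma and density must be positive")
        if not 0 <= self.g0 < 1:
            raise ValueError("g0 must be in [0, 1)")
        if self.buffer_km is None:
            self.buffer_km = 4.0 * self.sigma_km
        if self.buffer_km < 3.0 * self.sigma_km:
            raise ValueError("mask buffer must be at least 3 sigma beyond the detectors")


def grid_detectors(nx: int, ny: int, spacing_km: float, kind: str = "camera",
                   origin: tuple[float, float] = (0.0, 0.0)) -> pd.DataFrame:
    """Convenience: a rectangular array of detectors."""
    rows = []
    for i in range(nx):
        for j in range(ny):
            rows.append({"detector_id": f"{kind[:3]}{i * ny + j:03d}",
                         "x_km": origin[0] + i * spacing_km,
                         "y_km": origin[1] + j * spacing_km, "kind": kind})
    return pd.DataFrame(rows)


def gen_spatial_captures(scenario: SpatialScenario, seed: int = 0) -> CaptureData:
    """Simulate binary proximity detections from known SECR parameters.

    Activity centers are a homogeneous Poisson process at the scenario density
    over the mask extent; each animal is detected at each detector on each
    occasion independently with probability ``g0 * exp(-d^2 / (2 sigma^2))``.
    The true parameters (and the realized number of activity centers) are
    stored in ``metadata`` for recovery tests.
    """
    rng = np.random.default_rng(seed)
    det = scenario.detectors
    mask, cell_area = make_mask(det, scenario.buffer_km, scenario.mask_spacing_km)

    # simulate over the bounding rectangle of the mask region
    x0, x1 = det["x_km"].min() - scenario.buffer_km, det["x_km"].max() + scenario.buffer_km
    y0, y1 = det["y_km"].min() - scenario.buffer_km, det["y_km"].max() + scenario.buffer_km
    area = (x1 - x0) * (y1 - y0)
    n_animals = rng.poisson(scenario.density_per_100km2 / 100.0 * area)
    ax = rng.uniform(x0, x1, n_animals)
    ay = rng.uniform(y0, y1, n_animals)
    sexes = np.where(rng.random(n_animals) < scenario.female_fraction, "F", "M")

    dxy = det[["x_km", "y_km"]].to_numpy()
    d2 = (ax[:, None] - dxy[None, :, 0]) ** 2 + (ay[:, None] - dxy[None, :, 1]) ** 2
    g0s = np.array([(scenario.g0_by_sex or {}).get(s, scenario.g0) for s in sexes])
    sigs = np.array([(scenario.sigma_by_sex or {}).get(s, scenario.sigma_km) for s in sexes])
    p = g0s[:, None] * np.exp(-d2 / (2.0 * sigs[:, None] ** 2))

    rows = []
    counts = rng.binomial(scenario.n_occasions, p)      # animals x detectors
    occ_pool = np.arange(scenario.n_occasions)
    for i, j in zip(*np.nonzero(counts)):
        occs = rng.choice(occ_pool, size=counts[i, j], replace=False)
        for k in np.sort(occs):
            rows.append({"individual_id": f"an{i:04d}", "sex": sexes[i],
                         "detector_id": det["detector_id"].iloc[j], "occasion": int(k)})
    detections = pd.DataFrame(rows, columns=["individual_id", "sex", "detector_id", "occasion"])

    expected = float((1.0 - np.prod(1.0 - p, axis=1) ** scenario.n_occasions).sum()) if n_animals else 0.0
    meta = {
        "true_density_per_100km2": scenario.density_per_100km2,
        "true_g0": scenario.g0, "true_sigma_km": scenario.sigma_km,
        "n_activity_centers": int(n_animals),
        "expected_detected": expected,
        "seed": seed,
    }
    if expected < 1.0:
        meta["warning"] = "expected detections < 1; a fit will likely fail"
        warnings.warn(meta["warning"], stacklevel=2)
    return CaptureData(detectors=det.copy(), detections=detections,
                       n_occasions=scenario.n_occasions, mask=mask,
                       cell_area_km2=cell_area, metadata=meta)
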