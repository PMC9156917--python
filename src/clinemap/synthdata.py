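"""Synthetic occurrence records and covariate tables with known truth.

The generator emulates the statistical structure the analysis assumes: three
independent fully dominant loci whose allele frequencies follow geographic
clines along great-circle axes, spatially heterogeneous sampling effort
(a mixture of Gaussian hotspots), two record sources, and heavy B-locus
missingness among citizen-science records (images of wing undersides cannot
be scored for background colour). Environmental covariates are parametric
surfaces evaluated at record locations: temperature declines with absolute
latitude, solar radiation tracks temperature, and precipitation and soil
moisture are built to be strongly collinear (target correlation 0.9).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .cline import ClineModelSpec, ClineParams, cline_value
from .geodesy import EARTH_RADIUS_KM, Transect, gc_distance
from .records import LOCI, ClassCall, ColourRecord, Dataset, Source


@dataclass
class LocusCline:
    """Ground-truth cline at one locus: recessive allele frequency along an axis."""

    waypoints: list  # [(lat, lon), ...] great-circle axis
    params: ClineParams
    tails: str = "none"
    increasing: bool = True  # q rises along the axis when True

    def spec(self) -> ClineModelSpec:
        scaling = "none" if (self.params.pmin, self.params.pmax) == (0.0, 1.0) else "free"
        return ClineModelSpec(scaling=scaling, tails=self.tails)


@dataclass
class Hotspot:
    lat: float
    lon: float
    spread: float  # Gaussian sd, degrees
    weight: float = 1.0


@dataclass
class EnvModel:
    """Parametric covariate surfaces evaluated at record locations.

    bio01 (annual mean temperature, degC) = t0 + t_lat * |lat| + noise;
    bio20 (solar radiation) = s0 + s_t * bio01 + noise; bio12 (annual
    precipitation, mm) = p0 + p_lon * lon + noise; bio28 (soil moisture
    index) is constructed from standardized bio12 plus an orthogonalized
    latitude term to hit ``r_precip_soil`` exactly at the record level.
    """

    t0: float = 28.0
    t_lat: float = -0.35
    t_sd: float = 0.5
    s0: float = 180.0
    s_t: float = 2.5
    s_sd: float = 5.0
    p0: float = 800.0
    p_lon: float = 6.0
    p_sd: float = 5.0  # small iid part: the surface is mostly spatial, so
    # the built-in precipitation/soil-moisture correlation survives per-cell
    # averaging
    r_precip_soil: float = 0.9
    soil_mean: float = 0.5
    soil_sd: float = 0.15


DEFAULT_AXIS = [(5.0, 10.0), (-25.0, 40.0)]


def _default_loci() -> dict:
    # A and C share an axis with centres 1000 vs 2500 km apart (mismatched
    # clines); B is broad and partially scaled (extensive polymorphism).
    return {
        "A": LocusCline(DEFAULT_AXIS, ClineParams(c=1000.0, w=500.0), increasing=False),
        "B": LocusCline(
            DEFAULT_AXIS,
            ClineParams(c=2000.0, w=1500.0, pmin=0.1, pmax=0.9),
            increasing=False,
        ),
        "C": LocusCline(DEFAULT_AXIS, ClineParams(c=2500.0, w=500.0), increasing=False),
    }


def _default_hotspots() -> list:
    return [
        Hotspot(5.0, 10.0, 3.0, 2.0),
        Hotspot(-5.0, 20.0, 3.0, 2.0),
        Hotspot(-15.0, 30.0, 3.0, 1.5),
        Hotspot(-25.0, 38.0, 3.0, 1.5),
        Hotspot(0.0, 36.0, 4.0, 1.0),
    ]


@dataclass
class WorldSpec:
    loci: dict = field(default_factory=_default_loci)
    hotspots: list = field(default_factory=_default_hotspots)
    n_records: int = 20_000
    citizen_fraction: float = 0.32
    b_missing_citizen: float = 0.5
    env: EnvModel = field(default_factory=EnvModel)
    seed: int = 0
    uniform_region: tuple | None = None  # (lat_lo, lat_hi, lon_lo, lon_hi)

    def to_dict(self) -> dict:
        return {
            "loci": {
                loc: {
                    "waypoints": [list(w) for w in lc.waypoints],
                    "params": asdict(lc.params),
                    "tails": lc.tails,
                    "increasing": lc.increasing,
                }
                for loc, lc in self.loci.items()
            },
            "hotspots": [asdict(h) for h in self.hotspots],
            "n_records": self.n_records,
            "citizen_fraction": self.citizen_fraction,
            "b_missing_citizen": self.b_missing_citizen,
            "env": asdict(self.env),
            "seed": self.seed,
            "uniform_region": list(self.uniform_region) if self.uniform_region else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WorldSpec":
        return cls(
            loci={
                loc: LocusCline(
                    waypoints=[tuple(w) for w in v["waypoints"]],
                    params=ClineParams(**v["params"]),
                    tails=v.get("tails", "none"),
                    increasing=v.get("increasing", True),
                )
                for loc, v in d["loci"].items()
            },
            hotspots=[Hotspot(**h) for h in d["hotspots"]],
            n_records=d["n_records"],
            citizen_fraction=d["citizen_fraction"],
            b_missing_citizen=d["b_missing_citizen"],
            env=EnvModel(**d["env"]),
            seed=d["seed"],
            uniform_region=tuple(d["uniform_region"]) if d.get("uniform_region") else None,
        )


# ---------------------------------------------------------------------------
# vectorized projection onto a cline axis


def _axis_positions(lats, lons, waypoints) -> np.ndarray:
    """Cumulative along-axis position (km) for arrays of points.

    Points whose perpendicular projection falls outside every segment are
    clamped to the nearest endpoint's cumulative position, so frequencies
    plateau beyond the axis span.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    R = EARTH_RADIUS_KM
    lat_r = np.radians(lats)
    lon_r = np.radians(lons)
    n = lats.shape[0]
    best_metric = np.full(n, np.inf)
    best_along = np.zeros(n)
    cum = 0.0
    for a, b in zip(waypoints, waypoints[1:]):
        la, lo = np.radians(a[0]), np.radians(a[1])
        seg_len = float(gc_distance(a, b))
        # distance and bearing from segment start to every point
        dlat = lat_r - la
        dlon = lon_r - lo
        h = np.sin(dlat / 2) ** 2 + np.cos(la) * np.cos(lat_r) * np.sin(dlon / 2) ** 2
        d13 = 2 * np.arcsin(np.minimum(1.0, np.sqrt(h)))
        th13 = np.arctan2(
            np.sin(dlon) * np.cos(lat_r),
            np.cos(la) * np.sin(lat_r) - np.sin(la) * np.cos(lat_r) * np.cos(dlon),
        )
        lb, lob = np.radians(b[0]), np.radians(b[1])
        th12 = np.arctan2(
            np.sin(lob - lo) * np.cos(lb),
            np.cos(la) * np.sin(lb) - np.sin(la) * np.cos(lb) * np.cos(lob - lo),
        )
        xt = np.arcsin(np.sin(d13) * np.sin(th13 - th12)) * R
        with np.errstate(invalid="ignore", divide="ignore"):
            at = np.arccos(np.clip(np.cos(d13) / np.cos(xt / R), -1.0, 1.0)) * R
        at = np.where(np.cos(th13 - th12) < 0.0, -at, at)
        inside = (at >= 0.0) & (at <= seg_len)
        metric = np.where(
            inside,
            np.abs(xt),
            np.minimum(d13 * R, gc_distance(b, (lats, lons))),
        )
        better = metric < best_metric
        best_metric = np.where(better, metric, best_metric)
        best_along = np.where(better, cum + np.clip(at, 0.0, seg_len), best_along)
        cum += seg_len
    return best_along


def local_allele_freq(p, world: WorldSpec, locus: str):
    """Ground-truth recessive allele frequency q at point(s) p = (lat, lon)."""
    lc = world.loci[locus]
    lat, lon = p
    along = _axis_positions(np.atleast_1d(lat), np.atleast_1d(lon), lc.waypoints)
    q = cline_value(along, lc.params, lc.spec())
    q = np.asarray(q)
    if not lc.increasing:
        q = lc.params.pmin + lc.params.pmax - q
    return float(q[0]) if np.ndim(lat) == 0 else q


# ---------------------------------------------------------------------------
# sampling


def _sample_locations(world: WorldSpec, rng: np.random.Generator):
    n = world.n_records
    if world.uniform_region is not None:
        lat_lo, lat_hi, lon_lo, lon_hi = world.uniform_region
        lats = rng.uniform(lat_lo, lat_hi, n)
        lons = rng.uniform(lon_lo, lon_hi, n)
    else:
        w = np.array([h.weight for h in world.hotspots], float)
        idx = rng.choice(len(world.hotspots), size=n, p=w / w.sum())
        mu_lat = np.array([h.lat for h in world.hotspots])[idx]
        mu_lon = np.array([h.lon for h in world.hotspots])[idx]
        sd = np.array([h.spread for h in world.hotspots])[idx]
        lats = mu_lat + rng.normal(size=n) * sd
        lons = mu_lon + rng.normal(size=n) * sd
    lats = np.clip(lats, -90.0, 90.0)
    lons = (lons + 180.0) % 360.0 - 180.0
    return lats, lons


def sample_records(world: WorldSpec) -> Dataset:
    """Draw a synthetic dataset: hotspot-mixture locations, HWE genotypes at
    the local cline frequency with dominance collapsing, two sources, and
    B-locus missingness among citizen records."""
    rng = np.random.default_rng(world.seed)
    lats, lons = _sample_locations(world, rng)
    n = world.n_records
    citizen = rng.random(n) < world.citizen_fraction
    recessive = {}
    for locus in LOCI:
        q = local_allele_freq((lats, lons), world, locus)
        recessive[locus] = rng.random(n) < q * q  # HWE: recessive hom w.p. q^2
    b_lost = citizen & (rng.random(n) < world.b_missing_citizen)
    records = []
    for i in range(n):
        rc = {
            loc: ClassCall.RECESSIVE_HOM if recessive[loc][i] else ClassCall.DOMINANT_CLASS
            for loc in LOCI
        }
        if b_lost[i]:
            rc["B"] = ClassCall.MISSING
        records.append(
            ColourRecord(
                record_id=f"r{i:06d}",
                source=Source.CITIZEN if citizen[i] else Source.RESEARCH,
                latitude=float(lats[i]),
                longitude=float(lons[i]),
                calls=rc,
            )
        )
    return Dataset(records=records, provenance=f"synthetic world seed={world.seed}")


# ---------------------------------------------------------------------------
# environment


def record_covariates(lats, lons, env: EnvModel, rng: np.random.Generator):
    """Covariate values at record locations (dict of arrays)."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    bio01 = env.t0 + env.t_lat * np.abs(lats) + rng.normal(0, env.t_sd, lats.shape)
    bio20 = env.s0 + env.s_t * bio01 + rng.normal(0, env.s_sd, lats.shape)
    bio12 = env.p0 + env.p_lon * lons + rng.normal(0, env.p_sd, lats.shape)
    # soil moisture: exact sample correlation with precipitation by pairing
    # standardized bio12 with an orthogonalized independent component that is
    # half smooth-spatial (latitude) and half local iid, so the correlation
    # neither washes out nor saturates under per-cell averaging
    def _orth_unit(field, base):
        f = field - field.mean()
        f = f - (f @ base) / (base @ base) * base
        s = f.std()
        return f / s if s > 0 else np.zeros_like(f)

    z12 = (bio12 - bio12.mean()) / bio12.std()
    u_spatial = _orth_unit(np.abs(lats).astype(float), z12)
    u_local = _orth_unit(rng.normal(size=lats.shape), z12)
    u = (u_spatial + u_local) / np.sqrt(2.0)
    r = env.r_precip_soil
    bio28 = env.soil_mean + env.soil_sd * (r * z12 + np.sqrt(1.0 - r * r) * u)
    return {"bio01": bio01, "bio20": bio20, "bio12": bio12, "bio28": bio28}


def attach_environment(ds: Dataset, grid, world: WorldSpec, locus: str = "B"):
    """Build the env-cell table for a grid made from a world-sampled dataset.

    Covariates are generated at record locations and averaged per cell; the
    response y is the dominant-class frequency at ``locus`` and n_records the
    number of records scored there.
    """
    import pandas as pd

    from .gridding import assign_cell

    rng = np.random.default_rng(np.random.SeedSequence([world.seed, 7]))
    lats = np.array([r.latitude for r in ds])
    lons = np.array([r.longitude for r in ds])
    cov = record_covariates(lats, lons, world.env, rng)
    idx = [assign_cell(la, lo, grid.spec) for la, lo in zip(lats, lons)]
    df = pd.DataFrame({"cell": idx, **cov})
    means = {k: v for k, v in df.groupby("cell").mean(numeric_only=True).to_dict("index").items()}
    rows = []
    for cell_idx, cell in grid.cells.items():
        n = cell.n_scored.get(locus, 0)
        if n == 0 or cell_idx not in means:
            continue
        row = {
            "lon_idx": cell_idx[0],
            "lat_idx": cell_idx[1],
            "y": 1.0 - cell.f_rec_genotype(locus),
            "n_records": n,
            "centre_lon": cell.centre[1],
            "centre_lat": cell.centre[0],
        }
        for k in ("bio01", "bio20", "bio12", "bio28"):
            row[k] = means[cell_idx][k]
        rows.append(row)
    from .envassoc import ENV_COLUMNS

    return pd.DataFrame(rows)[ENV_COLUMNS]
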