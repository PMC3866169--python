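"""Synthetic barcode datasets with planted ground truth.

The generator emulates the statistical structure of a continental COI
barcode library: ~658 bp sequences, AT-rich base composition, a skewed
(zipf-like) distribution of specimens per species with mean about 8.8,
mean intraspecific K2P divergence about 0.7% and mean congeneric divergence
about 8.8%. Sequences evolve under an exact Kimura two-rate (K80) site
model over star phylogenies (a family root, genus roots, species ancestors,
specimen tips), so the expected pairwise K2P distance between any two tips
equals the sum of the planted branch lengths — the analyses downstream
consume only pairwise distances, which is why no full coalescent is
simulated.

Planted scenario events rewrite haplotypes and coordinates to create the
discordance patterns of interest: species pairs sharing identical or merely
co-clustered (diagnosable) barcodes, deep intraspecific splits in sympatry
or allopatry, mixtures that both share and split, and divergent singleton
haplotypes. The emitted :class:`SyntheticTruth` records the planted
partition, per-species category, sharing types and sympatry for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .records import BarcodeDataset, SpecimenRecord

# scenario kinds
SHARE_IDENTICAL = "SHARE_IDENTICAL"
SHARE_DIAGNOSABLE = "SHARE_DIAGNOSABLE"
SPLIT_ALLOPATRIC = "SPLIT_ALLOPATRIC"
SPLIT_SYMPATRIC = "SPLIT_SYMPATRIC"
MIXTURE = "MIXTURE"
SINGLETON_DIVERGENT = "SINGLETON_DIVERGENT"

_KINDS = {
    SHARE_IDENTICAL,
    SHARE_DIAGNOSABLE,
    SPLIT_ALLOPATRIC,
    SPLIT_SYMPATRIC,
    MIXTURE,
    SINGLETON_DIVERGENT,
}

#: lepidopteran-style AT-rich COI base composition (A, C, G, T)
BASE_FREQS = np.array([0.31, 0.16, 0.15, 0.38])

# K80 state bookkeeping: codes A=0, C=1, G=2, T=3
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNER_1 = np.array([1, 0, 1, 0])
_TV_PARTNER_2 = np.array([3, 2, 3, 2])

#: default region centroids (decimal degrees); chosen to span separations
#: from ~400 km to ~3000 km so allopatric scenarios can pick a realistic pair
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "FI": (64.0, 26.0),
    "UK": (53.0, -1.5),
    "DE": (51.0, 10.0),
    "FR": (46.5, 2.5),
    "IT": (42.8, 12.8),
    "ES": (40.0, -3.7),
    "Sar": (40.1, 9.0),
    "Sic": (37.5, 14.1),
}

#: coordinate scatter around a region centroid, degrees; offsets are clipped
#: at 2.5 sigma so a planted allopatric pair can never drift into sympatry
COORD_SIGMA_DEG = 0.25


@dataclass(frozen=True)
class Scenario:
    """One planted discordance event.

    ``divergence`` is the planted K2P divergence of the event (between the
    split lineages, or between the sharing species for diagnosable shares);
    ``km`` the approximate geographic separation for allopatric events.
    """

    kind: str
    divergence: float | None = None
    km: float = 600.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind: {self.kind}")


@dataclass
class ScenarioSpec:
    """Generator configuration; the defaults are the study conditions.

    ``mean_specimens`` and the divergence targets reproduce the dataset
    structure the analyses are calibrated against (8.8 barcodes per species
    on average with singletons allowed, 0.7% mean intraspecific and 8.8%
    mean congeneric divergence); ``ti_tv_ratio`` is the expected
    transition/transversion count ratio at low divergence (kappa/2).
    """

    n_species: int = 60
    n_genera: int | None = None
    mean_specimens: float = 8.8
    max_specimens: int = 46
    seq_length: int = 658
    target_intra: float = 0.007
    target_congeneric: float = 0.088
    target_intergeneric: float = 0.15
    ti_tv_ratio: float = 3.0
    scenarios: list[Scenario] = field(default_factory=list)
    regions: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")
        for name, v in (
            ("target_congeneric", self.target_congeneric),
            ("target_intergeneric", self.target_intergeneric),
        ):
            if not (0.0 < v < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if not (0.0 <= self.target_intra < 0.5):
            raise ValueError("target_intra must lie in [0, 0.5)")
        if self.target_intra >= self.target_congeneric / 2.0:
            raise ValueError(
                "infeasible spec: target_intra must be below half the congeneric "
                f"divergence ({self.target_intra} >= {self.target_congeneric / 2})"
            )
        if self.ti_tv_ratio <= 0:
            raise ValueError("ti_tv_ratio must be positive")
        n_share = sum(
            2 if s.kind in (SHARE_IDENTICAL, SHARE_DIAGNOSABLE, MIXTURE) else 1
            for s in self.scenarios
        )
        if n_share > self.n_species:
            raise ValueError("more scenario species than n_species")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    species_of: dict[str, str]
    planted_cluster_of: dict[str, str]
    category_of: dict[str, str]  # species -> MATCH/SHARE/SPLIT/MIXTURE
    sharing_pairs: list[dict]  # species_a, species_b, sharing_type, sympatric
    split_combos: list[dict]  # species, cluster_a, cluster_b, divergence, sympatric, singleton
    home_region: dict[str, str]  # species -> region code

    @property
    def n_planted_clusters(self) -> int:
        return len(set(self.planted_cluster_of.values()))

    def planted_labels(self, specimen_ids: list[str]) -> np.ndarray:
        lut = {c: k for k, c in enumerate(sorted(set(self.planted_cluster_of.values())))}
        return np.array([lut[self.planted_cluster_of[s]] for s in specimen_ids], dtype=int)


def k80_mismatch_probs(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) mismatch proportions
    between the endpoints of a K80 path of length ``d`` expected
    substitutions per site with rate ratio ``kappa``.

    These are also the per-site substitution probabilities for evolving a
    sequence along a branch of length ``d``; the K2P distance estimator
    inverts them exactly, so planted branch lengths are recovered in
    expectation.
    """
    if d < 0:
        raise ValueError("branch length must be nonnegative")
    e4 = math.exp(-4.0 * d / (kappa + 2.0))
    e2 = math.exp(-2.0 * (kappa + 1.0) * d / (kappa + 2.0))
    P = 0.25 + 0.25 * e4 - 0.5 * e2
    Q = 0.5 - 0.5 * e4
    return P, Q


def evolve(codes: np.ndarray, branch: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence along one branch under the K80 model."""
    if branch == 0.0:
        return codes.copy()
    P, Q = k80_mismatch_probs(branch, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    out[u < P] = _TS_PARTNER[codes[u < P]]
    m1 = (u >= P) & (u < P + Q / 2.0)
    out[m1] = _TV_PARTNER_1[codes[m1]]
    m2 = (u >= P + Q / 2.0) & (u < P + Q)
    out[m2] = _TV_PARTNER_2[codes[m2]]
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] for c in codes)


def _zipf_probs(mean: float, kmax: int) -> np.ndarray:
    """Truncated power-law pmf on 1..kmax with the requested mean."""
    k = np.arange(1, kmax + 1, dtype=float)

    def mean_at(a: float) -> float:
        w = k ** (-a)
        return float((k * w).sum() / w.sum())

    lo, hi = -3.0, 6.0
    if not (mean_at(hi) <= mean <= mean_at(lo)):
        raise ValueError(f"mean_specimens {mean} unreachable on 1..{kmax}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) > mean:
            lo = mid
        else:
            hi = mid
    w = k ** (-0.5 * (lo + hi))
    return w / w.sum()


class _Geo:
    """Coordinate sampling around region centroids with clipped scatter."""

    def __init__(self, regions: dict[str, tuple[float, float]], rng: np.random.Generator):
        self.regions = regions
        self.rng = rng

    def sample(self, region: str) -> tuple[float, float]:
        lat0, lon0 = self.regions[region]
        dlat, dlon = np.clip(
            self.rng.normal(0.0, COORD_SIGMA_DEG, size=2),
            -2.5 * COORD_SIGMA_DEG,
            2.5 * COORD_SIGMA_DEG,
        )
        return float(np.clip(lat0 + dlat, -90, 90)), float(lon0 + dlon)

    def distant_region(self, home: str, km: float) -> str:
        """The region whose centroid separation from home is nearest to
        ``km`` while exceeding the sympatry cutoff with margin."""
        from .geo import haversine_km

        lat0, lon0 = self.regions[home]
        best, best_err = None, math.inf
        for name, (lat, lon) in self.regions.items():
            if name == home:
                continue
            sep = haversine_km(lat0, lon0, lat, lon)
            if sep < 300.0:  # 100 km cutoff + 2x max scatter margin
                continue
            err = abs(sep - km)
            if err < best_err:
                best, best_err = name, err
        if best is None:
            raise ValueError(f"no region far enough from {home} for an allopatric event")
        return best


def generate(spec: ScenarioSpec) -> tuple[BarcodeDataset, SyntheticTruth]:
    """Generate a barcode dataset plus its planted truth. Deterministic in
    ``spec.seed``; same spec, same bytes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kappa = 2.0 * spec.ti_tv_ratio

    n_genera = spec.n_genera or max(1, round(spec.n_species / 10))
    genus_of_index = [g % n_genera for g in range(spec.n_species)]
    genus_names = [f"Genus{g + 1:02d}" for g in range(n_genera)]
    species_names = [
        f"{genus_names[genus_of_index[i]]} species{i + 1:03d}" for i in range(spec.n_species)
    ]
    subfamily_of_genus = {
        g: f"Subfamily{(k % 3) + 1}" for k, g in enumerate(genus_names)
    }

    # star phylogeny: family root -> genus roots -> species ancestors.
    # Branch lengths are set so that the expected *tip-to-tip* distances hit
    # the targets: conspecific tips differ by target_intra, congeneric tips
    # by target_congeneric, intergeneric tips by target_intergeneric.
    anc_branch = (spec.target_congeneric - spec.target_intra) / 2.0
    genus_branch = max(0.0, (spec.target_intergeneric - spec.target_congeneric) / 2.0)
    root = rng.choice(4, size=spec.seq_length, p=BASE_FREQS).astype(np.uint8)
    genus_roots = [evolve(root, genus_branch, kappa, rng) for _ in range(n_genera)]
    ancestors = [
        evolve(genus_roots[genus_of_index[i]], anc_branch, kappa, rng)
        for i in range(spec.n_species)
    ]

    counts = rng.choice(
        np.arange(1, spec.max_specimens + 1),
        size=spec.n_species,
        p=_zipf_probs(spec.mean_specimens, spec.max_specimens),
    )
    region_names = list(spec.regions)
    home = {
        species_names[i]: region_names[int(rng.integers(len(region_names)))]
        for i in range(spec.n_species)
    }
    geo = _Geo(spec.regions, rng)

    # ------------------------------------------------------------------
    # scenario casting: reserve species, same-genus pairs for sharing events
    # ------------------------------------------------------------------
    by_genus: dict[int, list[int]] = {}
    for i in range(spec.n_species):
        by_genus.setdefault(genus_of_index[i], []).append(i)
    free = set(range(spec.n_species))

    def take_pair() -> tuple[int, int]:
        for g in sorted(by_genus, key=lambda g: -len([i for i in by_genus[g] if i in free])):
            avail = [i for i in by_genus[g] if i in free]
            if len(avail) >= 2:
                a, b = avail[0], avail[1]
                free.discard(a)
                free.discard(b)
                return a, b
        raise ValueError("not enough same-genus species free for a sharing scenario")

    def take_one() -> int:
        i = min(free)
        free.discard(i)
        return i

    category = {sp: "MATCH" for sp in species_names}
    planted_cluster: dict[int, str] = {i: f"pc.{i:03d}" for i in range(spec.n_species)}
    # per species: list of (cluster_label, ancestor codes, region, n_specimens)
    plan: dict[int, list] = {}
    sharing_pairs: list[dict] = []
    split_combos: list[dict] = []
    shared_site: dict[int, tuple[float, float]] = {}  # forced collection site per species

    def split_divergence(s: Scenario) -> float:
        return s.divergence if s.divergence is not None else 0.05

    for s in spec.scenarios:
        if s.kind in (SHARE_IDENTICAL, SHARE_DIAGNOSABLE):
            a, b = take_pair()
            sa, sb = species_names[a], species_names[b]
            category[sa] = category[sb] = "SHARE"
            home[sb] = home[sa]
            planted_cluster[b] = planted_cluster[a]
            if s.kind == SHARE_IDENTICAL:
                ancestors[b] = ancestors[a].copy()
                sympatric = True
                site = geo.sample(home[sa])
                shared_site[a] = shared_site[b] = site
            else:
                d_share = s.divergence if s.divergence is not None else 0.008
                ancestors[b] = evolve(ancestors[a], d_share, kappa, rng)
                sympatric = True
                site = geo.sample(home[sa])
                shared_site[a] = shared_site[b] = site
            sharing_pairs.append(
                {
                    "species_a": min(sa, sb),
                    "species_b": max(sa, sb),
                    "sharing_type": "identical" if s.kind == SHARE_IDENTICAL else "diagnosable",
                    "sympatric": sympatric,
                }
            )
        elif s.kind in (SPLIT_ALLOPATRIC, SPLIT_SYMPATRIC, SINGLETON_DIVERGENT):
            i = take_one()
            sp = species_names[i]
            category[sp] = "SPLIT"
            d = split_divergence(s)
            anc2 = evolve(ancestors[i], d, kappa, rng)
            n = max(int(counts[i]), 2 if s.kind == SINGLETON_DIVERGENT else 4)
            if s.kind == SINGLETON_DIVERGENT:
                n1, n2 = n, 1
            else:
                n1 = n // 2
                n2 = n - n1
            if s.kind == SPLIT_SYMPATRIC:
                region2 = home[sp]
                sympatric = True
            else:
                region2 = geo.distant_region(home[sp], s.km)
                sympatric = False
            ca_lab, cb_lab = f"pc.{i:03d}.a", f"pc.{i:03d}.b"
            plan[i] = [
                (ca_lab, ancestors[i], home[sp], n1),
                (cb_lab, anc2, region2, n2),
            ]
            split_combos.append(
                {
                    "species": sp,
                    "cluster_a": ca_lab,
                    "cluster_b": cb_lab,
                    "divergence": d,
                    "sympatric": sympatric,
                    "singleton": s.kind == SINGLETON_DIVERGENT,
                }
            )
        elif s.kind == MIXTURE:
            a, b = take_pair()
            sa, sb = species_names[a], species_names[b]
            category[sa] = "MIXTURE"
            category[sb] = "SHARE"
            d = split_divergence(s)
            anc2 = evolve(ancestors[a], d, kappa, rng)
            region2 = geo.distant_region(home[sa], s.km)
            home[sb] = region2
            d_share = 0.008
            ancestors[b] = evolve(anc2, d_share, kappa, rng)
            n = max(int(counts[a]), 4)
            n1 = n // 2
            ca_lab, cb_lab = f"pc.{a:03d}.a", f"pc.{a:03d}.b"
            plan[a] = [
                (ca_lab, ancestors[a], home[sa], n1),
                (cb_lab, anc2, region2, n - n1),
            ]
            planted_cluster[b] = cb_lab
            site = geo.sample(region2)
            shared_site[b] = site
            shared_site[a] = site  # witnessed by a cluster-b specimen of A
            sharing_pairs.append(
                {
                    "species_a": min(sa, sb),
                    "species_b": max(sa, sb),
                    "sharing_type": "diagnosable",
                    "sympatric": True,
                }
            )
            split_combos.append(
                {
                    "species": sa,
                    "cluster_a": ca_lab,
                    "cluster_b": cb_lab,
                    "divergence": d,
                    "sympatric": False,
                    "singleton": False,
                }
            )

    # ------------------------------------------------------------------
    # emit specimens
    # ------------------------------------------------------------------
    records: list[SpecimenRecord] = []
    species_of: dict[str, str] = {}
    planted_cluster_of: dict[str, str] = {}
    identical_donor: dict[int, str] = {}

    for i in range(spec.n_species):
        sp = species_names[i]
        genus = genus_names[genus_of_index[i]]
        groups = plan.get(i, [(planted_cluster[i], ancestors[i], home[sp], int(counts[i]))])
        k = 0
        for cluster_label, anc, region, n_spec in groups:
            for j in range(n_spec):
                k += 1
                sid = f"S{i + 1:03d}-{k:02d}"
                codes = evolve(anc, spec.target_intra / 2.0, kappa, rng)
                # force the shared-haplotype witness for identical sharing
                lat, lon = geo.sample(region)
                if j == 0 and i in shared_site and cluster_label == planted_cluster[i]:
                    lat, lon = shared_site[i]
                if (
                    j == 0
                    and plan.get(i)
                    and cluster_label != groups[0][0]
                    and i in shared_site
                ):
                    lat, lon = shared_site[i]
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        species=sp,
                        genus=genus,
                        subfamily=subfamily_of_genus[genus],
                        region=region,
                        latitude=round(lat, 5),
                        longitude=round(lon, 5),
                        sequence=_decode(codes),
                    )
                )
                species_of[sid] = sp
                planted_cluster_of[sid] = cluster_label

    # identical sharing: copy one haplotype exactly across the pair so the
    # minimum interspecific distance is zero by construction
    for pair in [p for p in sharing_pairs if p["sharing_type"] == "identical"]:
        sa, sb = pair["species_a"], pair["species_b"]
        first_a = next(r for r in records if r.species == sa)
        idx_b = next(k for k, r in enumerate(records) if r.species == sb)
        records[idx_b] = replace(records[idx_b], sequence=first_a.sequence)

    # diagnosable sharing must stay diagnosable: nudge any accidental exact
    # duplicate across a diagnosable pair by one transition
    seq_by_species: dict[str, set] = {}
    for r in records:
        seq_by_species.setdefault(r.species, set()).add(r.sequence)
    for pair in sharing_pairs:
        if pair["sharing_type"] != "diagnosable":
            continue
        sa, sb = pair["species_a"], pair["species_b"]
        for k, r in enumerate(records):
            if r.species == sb and r.sequence in seq_by_species.get(sa, set()):
                codes = np.frombuffer(r.sequence.encode(), dtype=np.uint8)
                pos = int(rng.integers(len(r.sequence)))
                base = "ACGT".index(chr(codes[pos]))
                seq = r.sequence[:pos] + "ACGT"[_TS_PARTNER[base]] + r.sequence[pos + 1 :]
                records[k] = replace(r, sequence=seq)

    ds = BarcodeDataset(records=records)
    truth = SyntheticTruth(
        species_of=species_of,
        planted_cluster_of=planted_cluster_of,
        category_of=category,
        sharing_pairs=sharing_pairs,
        split_combos=split_combos,
        home_region=home,
    )
    return ds, truth


def survey_fixture(seed: int = 0) -> tuple[BarcodeDataset, SyntheticTruth]:
    """A ~60-species dataset with the study's discordance proportions.

    59 species: 40 exact matches, 8 sharing-only species (three identical
    sympatric pairs plus two mixture partners), 9 split species (six
    allopatric splits, one divergent allopatric singleton, two sympatric
    splits) and 2 mixtures — giving roughly 68/17/19 percent
    match/share/split with mixtures double-counted, and 9 of the 11
    within-species cluster pairs (82%) allopatric.
    """
    scenarios = (
        [Scenario(SHARE_IDENTICAL)] * 3
        + [Scenario(SPLIT_ALLOPATRIC, divergence=0.05, km=600.0)] * 6
        + [Scenario(SINGLETON_DIVERGENT, divergence=0.05, km=900.0)]
        + [Scenario(SPLIT_SYMPATRIC, divergence=0.05)] * 2
        + [Scenario(MIXTURE, divergence=0.05, km=700.0)] * 2
    )
    spec = ScenarioSpec(n_species=59, n_genera=6, scenarios=scenarios, seed=seed)
    return generate(spec)
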