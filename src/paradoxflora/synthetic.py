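"""Synthetic biogeographic world generator.

Builds a self-contained stand-in for the real data landscape of the
analysis — a taxonomic checklist backbone, a naturalization table
(species x country), national and global Red List statuses, point
occurrence records and a family-level tree — with the statistical
structure the downstream analysis assumes:

* an exact-count share of naturalized species threatened in >= 1 native
  country (``paradox_target``),
* a right-skewed Beta-distributed per-species fraction of the native
  range threatened, and
* a log10-log10 allometry between threatened native AOO and naturalized
  AOO, realized by construction of per-partition occupied-cell counts.

Countries are axis-aligned lon/lat rectangles tiling a region around the
equator; the analysis needs country membership, not realistic borders.
All randomness flows from one integer seed through named sub-streams, so
identical configs yield byte-identical worlds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GridSpec, WorldConfig
from .errors import ConfigError

# anchors of the allometry construction: the medians of naturalized and
# threatened AOO the generated world reproduces (km^2)
MEDIAN_NATURALIZED_AOO = 60593.0
MEDIAN_THREATENED_AOO = 37066.0
#: SD of the latent position along the allometric line (log10 km^2). The
#: observed scatter adds allometry_noise_sd isotropically on both axes, so
#: the major axis of the generated cloud equals allometry_slope exactly in
#: population (model II construction: both variables carry error).
LOG10_SD_LATENT = 0.8

#: weights of national categories drawn for threatened species-country pairs
THREAT_CAT = np.array(["VU", "EN", "CR", "EX", "EW"])
THREAT_CAT_P = np.array([0.45, 0.30, 0.20, 0.04, 0.01])

APOMICTIC_GENUS_FRACTION = 0.02

_SYL = ["ba", "ce", "da", "fi", "go", "lu", "mi", "no", "pe", "ra",
        "si", "tu", "ve", "xa", "ze", "ko", "la", "mu", "ni", "or"]
_EPI_SUFFIX = ["ensis", "flora", "phylla", "oides", "alba", "montana",
               "major", "minor", "rubra", "longa"]


def _syllables(idx: int, n: int = 3) -> str:
    out = []
    for _ in range(n):
        out.append(_SYL[idx % len(_SYL)])
        idx //= len(_SYL)
    return "".join(out)


def genus_name(idx: int) -> str:
    return _syllables(idx, 3).capitalize()


def epithet(idx: int) -> str:
    # 3 syllables give 8000 combinations; the suffix cycles on the quotient
    # so epithets stay unique for any realistic species count
    n = len(_SYL) ** 3
    return _syllables(idx % n, 3) + _EPI_SUFFIX[(idx // n) % len(_EPI_SUFFIX)]


def family_name(idx: int) -> str:
    return _syllables(idx, 2).capitalize() + "aceae"


def country_code(idx: int) -> str:
    return chr(ord("A") + idx // 26) + chr(ord("A") + idx % 26)


@dataclass
class SyntheticWorld:
    """All tables of one generated world, plus generation ground truth."""

    config: WorldConfig
    countries: pd.DataFrame          # code, lon_min, lat_min, lon_max, lat_max
    checklist: pd.DataFrame          # rawName, acceptedName, family, genus, isHybrid, status
    naturalizations: pd.DataFrame    # speciesName, countryCode
    national_statuses: pd.DataFrame  # speciesName, countryCode, category
    global_statuses: pd.DataFrame    # speciesName, category
    occurrences: pd.DataFrame        # Darwin-Core-style columns
    family_tree: str                 # Newick over family names
    apomictic_genera: list
    truth: pd.DataFrame = field(repr=False, default=None)

    def country_boxes(self):
        """Countries as shapely boxes keyed by code."""
        from shapely.geometry import box

        return {r.code: box(r.lon_min, r.lat_min, r.lon_max, r.lat_max)
                for r in self.countries.itertuples()}


def _make_countries(cfg: WorldConfig) -> pd.DataFrame:
    W = cfg.region_lon[1] - cfg.region_lon[0]
    H = cfg.region_lat[1] - cfg.region_lat[0]
    cols = max(1, round(math.sqrt(cfg.n_countries * W / H)))
    rows = math.ceil(cfg.n_countries / cols)
    tw, th = W / cols, H / rows
    recs = []
    for i in range(cfg.n_countries):
        r, c = divmod(i, cols)
        recs.append({
            "code": country_code(i),
            "lon_min": cfg.region_lon[0] + c * tw,
            "lat_min": cfg.region_lat[0] + r * th,
            "lon_max": cfg.region_lon[0] + (c + 1) * tw,
            "lat_max": cfg.region_lat[0] + (r + 1) * th,
        })
    return pd.DataFrame(recs)


def _interior_cells(country, grid: GridSpec):
    """Indices and areas of grid cells lying fully inside a country box."""
    cs = grid.cell_size_deg
    ox, oy = grid.origin
    ix0 = math.ceil((country.lon_min - ox) / cs - 1e-9)
    ix1 = math.floor((country.lon_max - ox) / cs + 1e-9) - 1
    iy0 = math.ceil((country.lat_min - oy) / cs - 1e-9)
    iy1 = math.floor((country.lat_max - oy) / cs + 1e-9) - 1
    ix = np.arange(ix0, ix1 + 1)
    iy = np.arange(iy0, iy1 + 1)
    xx, yy = np.meshgrid(ix, iy)
    cells = np.column_stack([xx.ravel(), yy.ravel()])
    areas = np.asarray(grid.cell_area_km2(cells[:, 1]))
    return cells, areas


def _random_tree(labels, rng: np.random.Generator) -> str:
    """Ultrametric random-join tree in Newick, branch lengths exponential."""
    clusters = [(lbl, 0.0) for lbl in labels]
    if len(clusters) == 1:
        return f"({clusters[0][0]}:1.0);"
    height = 0.0
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, ha) = clusters[i]
        (nb, hb) = clusters[j]
        height = max(height, ha, hb) + rng.exponential(0.5)
        merged = (f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})", height)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters[0][0] + ";"


def _exact_subset(rng: np.random.Generator, items: np.ndarray, fraction: float) -> np.ndarray:
    """A random subset whose size is round(fraction * n) — exact-count draw."""
    k = int(round(fraction * len(items)))
    if k == 0:
        return items[:0]
    return rng.choice(items, size=k, replace=False)


def _calibrate_construction(slope_target: float, sd_latent: float, noise_sd: float,
                            lo: float, hi_x: float, hi_y: float,
                            n_mc: int = 120_000, n_iter: int = 25,
                            damp: float = 0.5) -> tuple[float, float, float]:
    """Line slope, center and intercept of the latent construction such that
    the box-truncated cloud has major axis ``slope_target`` and marginal
    medians at the configured AOO anchors.

    Truncating a bivariate cloud to the representable AOO box (>= half a
    grid cell, <= what the region hosts) tilts its principal axis and
    shifts its medians, so the construction parameters cannot be used
    as-is; this solves for them by damped fixed-point iteration on a large
    deterministic Monte Carlo sample (undamped updates oscillate because
    the slope and intercept are coupled through the truncation). The
    internal sample is independent of the world seed, so calibration is a
    pure function of the config.
    """
    from .stats import ma_regression

    tx = math.log10(MEDIAN_NATURALIZED_AOO)
    ty = math.log10(MEDIAN_THREATENED_AOO)
    b, mu, c0 = slope_target, tx, ty - slope_target * tx
    rng = np.random.default_rng(np.random.SeedSequence(20250901))
    core0 = rng.normal(0.0, 1.0, n_mc)
    ex = rng.normal(0.0, 1.0, n_mc)
    ey = rng.normal(0.0, 1.0, n_mc)
    for _ in range(n_iter):
        core = mu + sd_latent * core0
        xs = core + noise_sd * ex
        ys = c0 + b * core + noise_sd * ey
        keep = (xs >= lo) & (xs <= hi_x) & (ys >= lo) & (ys <= hi_y)
        if keep.sum() < 1000:
            break  # box barely feasible; fall back to current parameters
        xk, yk = xs[keep], ys[keep]
        if noise_sd > 0:
            m = ma_regression(xk, yk).slope
            if m > 0:
                b *= (slope_target / m) ** damp
        mu += damp * (tx - float(np.median(xk)))
        c0 += damp * (ty - float(np.median(yk)))
    return b, mu, c0


def generate_world(config: WorldConfig, grid: GridSpec | None = None) -> SyntheticWorld:
    """Generate one synthetic world from a config.

    Determinism: the same config (including seed) always yields an
    identical world. Sub-streams per table are spawned from the master
    seed so each table's draws are independent.
    """
    if not isinstance(config, WorldConfig):
        raise ConfigError("config must be a WorldConfig")
    grid = grid or GridSpec()

    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["taxonomy", "roles", "statuses", "global", "occurrences", "tree"],
        ss.spawn(6))}

    countries = _make_countries(config)
    pools = {r.code: _interior_cells(r, grid) for r in countries.itertuples()}
    mean_cell_area = float(np.mean([a.mean() for _, a in pools.values()]))
    pool_size = min(len(c) for c, _ in pools.values())
    all_codes = countries["code"].to_numpy()

    # ---- taxonomy: families (Zipf-skewed sizes), genera, species names ----
    rng = streams["taxonomy"]
    n_genera = max(config.n_families, config.n_species // 8)
    genus_family = rng.integers(0, config.n_families, size=n_genera)
    fam_weights = 1.0 / np.arange(1, config.n_families + 1)
    fam_weights /= fam_weights.sum()
    sp_family = rng.choice(config.n_families, size=config.n_species, p=fam_weights)
    genera_by_family = {f: np.flatnonzero(genus_family == f) for f in range(config.n_families)}
    species = []
    for i in range(config.n_species):
        fam = int(sp_family[i])
        candidates = genera_by_family[fam]
        if len(candidates) == 0:  # family without genus: dedicate one
            gidx = n_genera + fam
        else:
            gidx = int(rng.choice(candidates))
        name = f"{genus_name(gidx)} {epithet(i)}"
        species.append({"acceptedName": name, "genus": genus_name(gidx),
                        "family": family_name(fam)})
    sp = pd.DataFrame(species)
    if sp["acceptedName"].duplicated().any():
        raise ConfigError("n_species exceeds the unique-name capacity of the "
                          "name generator")
    all_genera = sorted(sp["genus"].unique())
    n_apo = max(1, int(round(APOMICTIC_GENUS_FRACTION * len(all_genera))))
    apomictic = sorted(rng.choice(all_genera, size=n_apo, replace=False).tolist())

    checklist = sp.copy()
    checklist.insert(0, "rawName", checklist["acceptedName"])
    checklist["isHybrid"] = False
    checklist["status"] = "accepted"

    # ---- roles: naturalized / paradox designation (exact-count) ----
    rng = streams["roles"]
    idx_all = np.arange(config.n_species)
    nat_idx = np.sort(_exact_subset(rng, idx_all, config.naturalized_fraction))
    is_nat = np.zeros(config.n_species, bool)
    is_nat[nat_idx] = True
    par_idx = np.sort(_exact_subset(rng, nat_idx, config.paradox_target))
    is_par = np.zeros(config.n_species, bool)
    is_par[par_idx] = True
    non_nat = idx_all[~is_nat]
    loss_idx = np.sort(_exact_subset(rng, non_nat, config.threat_rate_non_naturalized))
    is_loss = np.zeros(config.n_species, bool)
    is_loss[loss_idx] = True
    nt_only = is_nat & ~is_par & (rng.random(config.n_species) < config.nt_only_rate)

    # ---- statuses + AOO construction ----
    rng = streams["statuses"]
    a_shape, b_shape = config.pct_threat_shape

    # Paradox AOO pairs: latent position along the allometric line plus
    # isotropic log10 noise, rejection-sampled inside the representable box
    # (at least half a grid cell on both axes, at most what the region can
    # host). Clamping sub-cell draws up to the 1-cell floor would pile mass
    # on the boundary and bias the realized major axis upward; truncating
    # the latent distribution leaves the axis at allometry_slope. The anchor
    # medians are adjusted for the truncation so realized medians stay near
    # the configured anchors.
    n_par_total = int(is_par.sum())
    lo_box = math.log10(0.5 * mean_cell_area)
    hi_nat = math.log10(1200 * mean_cell_area)
    hi_thr = math.log10(400 * mean_cell_area)
    b_line, mu_adj, c0_adj = _calibrate_construction(
        config.allometry_slope, LOG10_SD_LATENT, config.allometry_noise_sd,
        lo_box, hi_nat, hi_thr)
    log_nat_par = np.empty(n_par_total)
    log_thr_par = np.empty(n_par_total)
    need = np.ones(n_par_total, bool)
    rounds = 0
    while need.any():
        rounds += 1
        if rounds > 1000:
            raise ConfigError("cannot place AOO pairs inside the region; "
                              "enlarge the region or shrink the grid cells")
        k = int(need.sum())
        core = rng.normal(mu_adj, LOG10_SD_LATENT, k)
        xs = core + rng.normal(0, config.allometry_noise_sd, k)
        ys = (c0_adj + b_line * core
              + rng.normal(0, config.allometry_noise_sd, k))
        okm = (xs >= lo_box) & (xs <= hi_nat) & (ys >= lo_box) & (ys <= hi_thr)
        idx = np.flatnonzero(need)[okm]
        log_nat_par[idx] = xs[okm]
        log_thr_par[idx] = ys[okm]
        need[idx] = False
    p_par = np.clip(rng.beta(a_shape, b_shape, n_par_total), 0.01, 0.99)
    par_rank = np.cumsum(is_par) - 1

    nat_rows, stat_rows, occ_batches = [], [], []
    truth_rows = []
    occ_rng = streams["occurrences"]

    def sample_points(code: str, n_cells: int, n_extra_rng) -> np.ndarray:
        """n_cells distinct cells in a country, 1-2 points per cell."""
        cells, _ = pools[code]
        take = min(n_cells, len(cells))
        chosen = cells[occ_rng.choice(len(cells), size=take, replace=False)]
        extra = chosen[n_extra_rng.random(take) < 0.3]
        pts_cells = np.vstack([chosen, extra])
        u = occ_rng.random((len(pts_cells), 2))
        lon = grid.origin[0] + (pts_cells[:, 0] + u[:, 0]) * grid.cell_size_deg
        lat = grid.origin[1] + (pts_cells[:, 1] + u[:, 1]) * grid.cell_size_deg
        return np.column_stack([lon, lat])

    bounds = {r.code: (r.lon_min, r.lat_min, r.lon_max, r.lat_max)
              for r in countries.itertuples()}

    def scatter_points(code: str, n: int) -> np.ndarray:
        x0, y0, x1, y1 = bounds[code]
        u = occ_rng.random((n, 2))
        return np.column_stack([x0 + u[:, 0] * (x1 - x0),
                                y0 + u[:, 1] * (y1 - y0)])

    def split_cells(total: int, codes) -> list[int]:
        """Distribute a cell budget over countries, capped by pool size."""
        out = []
        remaining = total
        for k, code in enumerate(codes):
            cap = len(pools[code][0])
            share = min(cap, math.ceil(remaining / (len(codes) - k)))
            out.append(share)
            remaining -= share
        return out

    lognorm_mu = math.log(config.occ_per_species_mean) - 0.5

    for i in range(config.n_species):
        name = sp.at[i, "acceptedName"]
        threatened_here = bool(is_par[i] or is_loss[i])
        # country roles
        if is_par[i]:
            n_native = 2 + int(rng.poisson(1.0))
            p = float(p_par[par_rank[i]])
        else:
            n_native = 1 + int(rng.poisson(1.2))
            p = (float(np.clip(rng.beta(a_shape, b_shape), 0.01, 0.99))
                 if is_loss[i] else 0.0)
        if threatened_here:
            n_thr = max(1, min(n_native - (0 if p > 0.9 else 1), round(p * n_native)))
            n_thr = max(1, n_thr)
        else:
            n_thr = 0

        aoo_nat = aoo_thr = aoo_ok = None
        if is_par[i]:
            j = par_rank[i]
            aoo_nat, aoo_thr = 10.0 ** log_nat_par[j], 10.0 ** log_thr_par[j]
            aoo_ok = aoo_thr * (1.0 - p) / p
            cells_nat = max(1, round(aoo_nat / mean_cell_area))
            cells_thr = max(1, round(aoo_thr / mean_cell_area))
            # derive the ok budget from the *realized* threatened cell count
            # so the threatened share of native cells stays at p even when
            # rounding perturbs a tiny threatened AOO
            cells_ok = max(0, round(cells_thr * (1.0 - p) / p))
            # grow country allocations to host the cell budgets; threatened
            # and naturalized budgets take precedence over the ok budget
            n_thr = max(n_thr, math.ceil(cells_thr / (0.9 * pool_size)))
            n_nat_c = max(1 + int(rng.poisson(0.8)),
                          math.ceil(cells_nat / (0.9 * pool_size)))
            avail_ok = len(all_codes) - n_thr - n_nat_c
            n_ok_c = min(max(n_native - n_thr, math.ceil(cells_ok / (0.9 * pool_size)), 1),
                         max(avail_ok, 0))
            n_native = n_thr + n_ok_c
        else:
            n_nat_c = 1 + int(rng.poisson(0.8)) if is_nat[i] else 0
            n_native = min(n_native, len(all_codes) - n_nat_c)
            n_native = max(n_native, n_thr, 1)
        perm = rng.permutation(all_codes)
        native_codes = perm[:n_native]
        nat_codes = perm[n_native:n_native + n_nat_c]
        thr_codes = native_codes[:n_thr]
        ok_codes = native_codes[n_thr:]

        # naturalization rows
        for code in nat_codes:
            nat_rows.append((name, code))
        # national statuses: native countries only
        thr_cats = rng.choice(THREAT_CAT, size=n_thr, p=THREAT_CAT_P)
        for code, cat in zip(thr_codes, thr_cats):
            stat_rows.append((name, code, cat))
        ok_cats = rng.choice(["LC", "DD"], size=len(ok_codes), p=[0.88, 0.12])
        if nt_only[i] and len(ok_codes) > 0:
            ok_cats = ok_cats.copy()
            ok_cats[0] = "NT"
        for code, cat in zip(ok_codes, ok_cats):
            stat_rows.append((name, code, cat))

        # occurrences
        pts = []
        if is_par[i]:
            for code, k in zip(thr_codes, split_cells(cells_thr, thr_codes)):
                if k > 0:
                    pts.append((sample_points(code, k, occ_rng), code, "native"))
            if len(ok_codes) and cells_ok > 0:
                for code, k in zip(ok_codes, split_cells(cells_ok, ok_codes)):
                    if k > 0:
                        pts.append((sample_points(code, k, occ_rng), code, "native"))
            for code, k in zip(nat_codes, split_cells(cells_nat, nat_codes)):
                if k > 0:
                    pts.append((sample_points(code, k, occ_rng), code, "introduced"))
        else:
            n_occ = max(1, int(round(occ_rng.lognormal(lognorm_mu, 1.0))))
            codes = list(native_codes) + list(nat_codes)
            weights = np.array([0.7 / max(1, len(native_codes))] * len(native_codes)
                               + [0.3 / max(1, len(nat_codes))] * len(nat_codes))
            weights /= weights.sum()
            counts = occ_rng.multinomial(n_occ, weights)
            for code, k in zip(codes, counts):
                if k > 0:
                    means = "native" if code in set(native_codes) else "introduced"
                    pts.append((scatter_points(code, k), code, means))
        for xy, code, means in pts:
            occ_batches.append((name, code, means, xy))

        truth_rows.append({
            "acceptedName": name, "family": sp.at[i, "family"], "genus": sp.at[i, "genus"],
            "is_naturalized": bool(is_nat[i]), "is_paradox": bool(is_par[i]),
            "is_net_loss": bool(is_loss[i]), "nt_only": bool(nt_only[i]),
            "pct_target": p * 100.0 if threatened_here else np.nan,
            "aoo_naturalized_target": aoo_nat, "aoo_threatened_target": aoo_thr,
            "aoo_native_ok_target": aoo_ok,
        })

    # ---- global statuses ----
    rng = streams["global"]
    from .threat import SEVERITY, IUCNCategory, worst_category

    stat_df = pd.DataFrame(stat_rows, columns=["speciesName", "countryCode", "category"])
    worst = stat_df.groupby("speciesName")["category"].agg(
        lambda c: worst_category(c).value)
    glob_rows = []
    par_names = sp.loc[is_par, "acceptedName"].to_numpy()
    glob_threat = set(_exact_subset(rng, par_names, config.global_threat_share))
    # share of remaining paradox species that are globally NT: tuned so the
    # with-NT global share exceeds the without-NT share by ~0.8pp of the
    # naturalized flora
    glob_nt = set(_exact_subset(rng, np.array(sorted(set(par_names) - glob_threat)), 0.029))
    for i in range(config.n_species):
        name = sp.at[i, "acceptedName"]
        if name in glob_threat:
            w = IUCNCategory(worst.get(name, "VU"))
            if w is IUCNCategory.EX and rng.random() < 0.5:
                cat = "EW"
            else:
                ceiling = min(SEVERITY[w], SEVERITY[IUCNCategory.CR])
                options = [c for c in ("VU", "EN", "CR")
                           if SEVERITY[IUCNCategory(c)] <= ceiling]
                cat = str(rng.choice(options)) if options else "VU"
        elif name in glob_nt:
            cat = "NT"
        elif is_nat[i]:
            cat = str(rng.choice(["LC", "NE", "DD"], p=[0.6, 0.3, 0.1]))
        else:
            cat = str(rng.choice(["LC", "NE"], p=[0.3, 0.7]))
        glob_rows.append((name, cat))

    tree = _random_tree([family_name(f) for f in range(config.n_families)], streams["tree"])

    if occ_batches:
        sizes = [len(xy) for _, _, _, xy in occ_batches]
        coords = np.concatenate([xy for _, _, _, xy in occ_batches])
        occurrences = pd.DataFrame({
            "scientificName": np.repeat([n for n, _, _, _ in occ_batches], sizes),
            "decimalLongitude": np.round(coords[:, 0], 6),
            "decimalLatitude": np.round(coords[:, 1], 6),
            "countryCode": np.repeat([c for _, c, _, _ in occ_batches], sizes),
            "establishmentMeans": np.repeat([m for _, _, m, _ in occ_batches], sizes),
        })
    else:
        occurrences = pd.DataFrame(columns=["scientificName", "decimalLongitude",
                                            "decimalLatitude", "countryCode",
                                            "establishmentMeans"])
    return SyntheticWorld(
        config=config,
        countries=countries,
        checklist=checklist,
        naturalizations=pd.DataFrame(nat_rows, columns=["speciesName", "countryCode"]),
        national_statuses=stat_df,
        global_statuses=pd.DataFrame(glob_rows, columns=["speciesName", "category"]),
        occurrences=occurrences,
        family_tree=tree,
        apomictic_genera=apomictic,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------- noise ----

def inject_name_noise(world: SyntheticWorld, synonym_rate: float = 0.0,
                      hybrid_rate: float = 0.0, seed: int = 0) -> SyntheticWorld:
    """Replace a fraction of table names with registered synonyms and mark a
    fraction of species as hybrids.

    Synonym noise: for each chosen species, a synonym name is invented,
    registered in the checklist (status=synonym) and substituted for the
    accepted name in the naturalization and status tables, so that
    harmonization can invert the replacement exactly.

    Hybrid noise: chosen species have the hybrid marker inserted into their
    name consistently everywhere (checklist and all tables) and their
    checklist flag set, so the exclusion rule fires on them.
    """
    for rate, label in ((synonym_rate, "synonym_rate"), (hybrid_rate, "hybrid_rate")):
        if not (0.0 <= rate <= 1.0):
            raise ConfigError(f"{label} must lie in [0, 1], got {rate!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    accepted = world.checklist.loc[world.checklist["status"] == "accepted",
                                   "acceptedName"].to_numpy()
    existing = set(accepted)

    checklist = world.checklist.copy()
    tables = {name: getattr(world, name).copy()
              for name in ("naturalizations", "national_statuses", "global_statuses")}

    syn_species = _exact_subset(rng, accepted, synonym_rate)
    syn_rows = []
    for name in syn_species:
        genus, epi = name.split(" ", 1)
        syn = f"{genus} {epi}var"
        while syn in existing:
            syn += "a"
        existing.add(syn)
        row = checklist.loc[checklist["acceptedName"] == name].iloc[0]
        syn_rows.append({"rawName": syn, "acceptedName": name, "family": row["family"],
                         "genus": row["genus"], "isHybrid": False, "status": "synonym"})
        for tbl in tables.values():
            tbl.loc[tbl["speciesName"] == name, "speciesName"] = syn
    if syn_rows:
        checklist = pd.concat([checklist, pd.DataFrame(syn_rows)], ignore_index=True)

    hyb_species = set(_exact_subset(rng, accepted, hybrid_rate))
    rename = {}
    for name in hyb_species:
        genus, epi = name.split(" ", 1)
        rename[name] = f"{genus} ×{epi}"
    if rename:
        for col in ("rawName", "acceptedName"):
            checklist[col] = checklist[col].replace(rename)
        checklist.loc[checklist["acceptedName"].isin(rename.values()), "isHybrid"] = True
        for tbl in tables.values():
            tbl["speciesName"] = tbl["speciesName"].replace(rename)
        occ = world.occurrences.copy()
        occ["scientificName"] = occ["scientificName"].replace(rename)
        truth = world.truth.copy()
        truth["acceptedName"] = truth["acceptedName"].replace(rename)
    else:
        occ = world.occurrences
        truth = world.truth

    return replace(world, checklist=checklist, occurrences=occ, truth=truth, **tables)


# -------------------------------------------------------------- writers ----

def countries_geojson(countries: pd.DataFrame) -> dict:
    feats = []
    for r in countries.itertuples():
        ring = [[r.lon_min, r.lat_min], [r.lon_max, r.lat_min],
                [r.lon_max, r.lat_max], [r.lon_min, r.lat_max],
                [r.lon_min, r.lat_min]]
        feats.append({"type": "Feature",
                      "properties": {"code": r.code},
                      "geometry": {"type": "Polygon", "coordinates": [ring]}})
    return {"type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
            "features": feats}


def load_countries_geojson(path) -> pd.DataFrame:
    import json

    with open(path) as fh:
        gj = json.load(fh)
    recs = []
    for feat in gj["features"]:
        xs, ys = zip(*feat["geometry"]["coordinates"][0])
        recs.append({"code": feat["properties"]["code"],
                     "lon_min": min(xs), "lat_min": min(ys),
                     "lon_max": max(xs), "lat_max": max(ys)})
    return pd.DataFrame(recs)


def write_world(world: SyntheticWorld, out_dir) -> dict:
    """Write all world artifacts as plain-text files; returns name->path."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def csv(name, df):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    csv("checklist", world.checklist)
    csv("naturalizations", world.naturalizations)
    csv("national_statuses", world.national_statuses)
    csv("global_statuses", world.global_statuses)
    csv("occurrences", world.occurrences)
    p = out / "countries.geojson"
    with open(p, "w") as fh:
        json.dump(countries_geojson(world.countries), fh)
    paths["countries"] = p
    p = out / "family_tree.nwk"
    p.write_text(world.family_tree + "\n")
    paths["family_tree"] = p
    p = out / "apomictic_genera.txt"
    p.write_text("\n".join(world.apomictic_genera) + "\n")
    paths["apomictic_genera"] = p
    return paths
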