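# sympatria

Occurrence-based analysis of congeneric sympatry and body-size divergence in
a species-rich clade: from raw point occurrences and a dated phylogeny to
bioregions, a directed sympatry matrix, a signed "divergent sympatry"
statistic, and phylogenetic comparative fits — with a first-class synthetic
data generator so the whole pipeline is testable end to end without any
external database.

## Who this is for

Researchers asking whether co-occurring congeners differ in body size more
(or less) than expected from the sizes available in the genus — the spatial
signature of character displacement or size-assortative coexistence — using
nothing but georeferenced occurrence records (GBIF-style `species, longitude,
latitude` tables), a Newick phylogeny, and a table of body sizes
(snout-to-vent length, SVL, in mm, the standard lizard measure).

## What it computes

1. **Cleaning** — occurrence records outside their species' range polygon
   are removed (boundary-inclusive point-in-polygon); species without
   polygons are reported, never silently kept.
2. **Bioregions** — occurrences are binned on an adaptive grid (4° cells
   halving to 2° when a cell holds more than 100 points, re-merging
   quadrants below 10), linked into a weighted species×cell bipartite
   network, and partitioned into bioregions by seeded two-mode label
   propagation. Per region: spherical area (km²), area-weighted centroid
   northing (km), elevation SD (m), biome count, and size-class counts, plus
   Spearman/Pearson richness correlations and an OLS of richness on biome
   count.
3. **Sympatry (directed rule)** — species *a* is sympatric with *b* when at
   least 10 of *a*'s points lie within 5 km (inclusive, haversine on a
   sphere of radius 6371.0088 km) of some *b* point. The rule is
   directional: S[a→b] and S[b→a] can differ.
4. **Divergent sympatry** — sizes are split into small/medium/large by
   Fisher–Jenks natural breaks; for each focal species with sympatric
   congeners,

   χ² = Σ_c (O_c − E_c)² / E_c,

   where O_c counts sympatric congeners in size class c and E_c is the
   genus-wide class frequency scaled to the focal's congener count. The
   score is multiplied by −1 when the focal's own class is over-represented
   (convergent sympatry). Sign-category and per-bioregion composition
   goodness-of-fit tests follow.
5. **Comparative methods** — ML fits of Brownian motion (closed form),
   Ornstein–Uhlenbeck, and Early-burst models to SVL; Pagel's λ;
   GLS ancestral states (root size); intercept-only PGLS residuals
   (phylogenetically detrended size) correlated against the divergence
   scores; and per-bioregion MPD (mean pairwise patristic distance) with
   standardized effect sizes against a tip-shuffling null — negative SES
   means phylogenetic clustering.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic system:
a 40-species Yule clade, SVL diffusing from a 76 mm root at σ² = 8 mm²/unit,
100-km circular ranges on a subtropical domain, and a size-structured
co-occurrence design in which half the large species overlap each other and
the rest overlap small species.

```
python analysis/01_simulate.py
python analysis/02_bioregions.py
python analysis/03_sympatry_divergence.py
python analysis/04_comparative_evolution.py
python analysis/05_dispersion.py
```

Output from a run (seed 1):

```
simulated 40 species, 8000 occurrence points
30 bioregions over 67 grid cells
size-class breaks at 70.7 and 79.4 mm; counts {'small': 7, 'medium': 13, 'large': 20}
20/40 species have at least one sympatric congener
  small: 7/7 positive (divergent); sign-category chi2 14.00, p 0.000912
  large: 7/13 positive (divergent); sign-category chi2 6.62, p 0.0366
BM: logL -91.58, sigma2 8.61
OU: logL -91.58, sigma2 8.61 alpha=0.0000
Pagel's lambda 1.000 (logL -91.26)
ancestral root SVL 78.7 mm
```

Reading this: every small species placed over a large species' range is
recovered as positively divergent; the OU pull parameter collapses to 0, so
OU reduces to the BM that actually generated the data; λ ≈ 1 and the
reconstructed root (78.7 mm) sits near the simulated 76 mm root; and σ̂²
(8.61) is close to the generating rate of 8.

The same pipeline runs on real data from one YAML config:

```
sympatria run --config run.yaml
```

(see `sympatria --help` for the per-stage subcommands `simulate`, `sympatry`,
`divergence`, `bioregions`, `comparative`, `dispersion`).

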