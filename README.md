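# retroflux

Quantitative analysis linking **transcript regulation** to **de novo protein
synthesis** in high-light acclimation experiments — the retrograde-signalling
design in which low-light (L, 8 µmol quanta·m⁻²·s⁻¹) and normal-light
(N, 80) acclimated *Arabidopsis thaliana* plants are shifted to high light
(H, 800), giving four treatments (L, L→H, N, N→H) measured on 2D gels in two
channels: silver stain (steady-state proteome) and ³⁵S-methionine
autoradiograms (newly synthesized protein), alongside transcript log2 fold
changes from arrays.

The package is for proteomics / systems-biology analysts who have spot-table
quantifications (spots × gels) from such a multi-channel 2D-gel design and
want the full downstream analysis:

1. **Total-intensity normalization** — each spot becomes a share of its
   gel's total intensity (gels are loaded with equal protein or cpm).
2. **log2 fold changes** per treatment contrast (N/L, N→H/N, L→H/L,
   L→H/N→H), `F_POI = log2(mean_num / mean_den)` over replicate gels.
3. **One-way ANOVA filter** across the four treatments (raw p ≤ 0.01,
   df₁ = 3, df₂ = 8 at three replicates, no multiple-testing correction).
4. **Archetype clustering** — per-spot z-scoring, euclidean distance,
   complete linkage, tree cut at k = 4 regulation archetypes
   (1: down in both H shifts; 2: up in both; 3: up in N→H, down in L→H;
   4: N-type vs L-type plants).
5. **Venn deviation bookkeeping** — per condition, spots whose mean
   z-score deviates from the all-treatment average by ≥ θ, decomposed into
   exclusive overlap regions with integer percentages.
6. **Response-factor concordance** — the statistic at the core of the
   analysis. Per method m ∈ {transcript, de novo} and shift contrast
   c ∈ {N→H/N, L→H/L}, each fold change is scaled by the extreme reaction
   of its sign over the analysed feature set,

       v_m(c) = F_POI / |F_Ext(sign(F_POI), c, m)|  ∈ [-1, 1],

   and summed into the response factor

       R_m = v_m(N→H/N) + v_m(L→H/L)  ∈ [-2, 2],

   where +2 means maximal up-regulation in both shifts and −2 maximal
   down-regulation. A feature is **discordant** (translationally
   controlled) when its point (R_transcript, R_de_novo) leaves the diagonal
   band: d = |R_de_novo − R_transcript| > 0.5.

Because no spot quantifications are deposited for the original experiment,
the package ships a **synthetic-data generator** that emulates the 12-gel
design with planted archetypes, lognormal replicate noise, a dominant
RubisCO-like spot (a fixed share of the N/N→H gel intensity), autoradiogram
dropout (ND spots) and a planted fraction of transcript/translation-
decoupled features — with full ground truth, so every stage is testable.
The printed reference tables (treatment physiology; the 49 identified
polypeptides; the archetype catalog) are packaged as TSV fixtures under
`retroflux/data/`.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (seed 42), writing tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_normalize_foldchange.py
python analysis/03_anova_cluster.py
python analysis/04_venn_deviations.py
python analysis/05_concordance.py
python analysis/06_fixture_statistics.py
python analysis/07_calibration_checks.py
```

Selected output:

```
108 of 112 tested spots significant (one-way ANOVA, p ≤ 0.01)
cluster sizes: {1: 5, 2: 51, 3: 13, 4: 39}
...
75 of 112 features discordant (fraction 0.670, cutoff |ΔR| > 0.5)
planted discordant fraction among scored features: 0.643; per-feature call agreement with truth: 0.973
...
(a) null type-I error: 0.0090 significant at p ≤ 0.01 (nominal 0.01 ± 0.0067)
(b) archetype recovery: ARI 1.000 over 398 clustered spots (filter power 0.995)
(c) discordance recovery: 130/200 = 0.650 (planted 0.65)
```

Reading this: of 129 simulated spots, 17 are ND in the autoradiogram and
112 reach the ANOVA; nearly all pass because effects are planted in most
features *and* the dominant spot compositionally shifts every other spot in
the N-gels. The concordance stage estimates 67% translationally controlled
features against a planted 64% among scored features, agreeing with the
per-feature truth for 97% of features. The calibration studies show the
raw-p filter holds its nominal type-I error on a pure null, archetypes are
recovered perfectly at the study's effect/noise ratio, and a planted 65%
discordant fraction is recovered exactly.

The same pipeline runs from a shell on user tables:

```sh
retroflux simulate --out sim --seed 42
retroflux all --skip-simulate \
    --autoradiogram sim/autoradiogram_spots.tsv \
    --silver sim/silver_spots.tsv \
    --transcript sim/transcript_log2fc.tsv \
    --out report
```

Fixture-derived statistics (`analysis/06_fixture_statistics.py`): L-plants
hold 38% of the RNA, 48% of the protein and 61% of the chlorophyll of
N-plants; the catalog lists 49 identified polypeptides, 8 of them never
detected in the autoradiograms, 80% chloroplast-localized.

## Layout

```
src/retroflux/      library: simulate, normalize, differential, venn,
                    concordance, fixtures, report, cli (+ data/ fixtures)
analysis/           numbered narrative drivers (simulate → ... → calibration)
tests/              pytest suite (unit, property and study-level tests)
scripts/            acceptance.py
docs/methods.md     model, parameters, numerical choices, limitations
```
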