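# vocsig

Individual vocal signatures in cat meows and purrs: a tested, reusable
pipeline for asking *how much identity information a call type carries* and
*how variable a group's calls are* — built for bioacousticians comparing
call types or taxa.

Domestic cats produce two very different close-range vocalisations: the
**meow** (tonal, harmonic, F0 roughly 208–1000 Hz, typically < 2.5 s) and
the **purr** (a continuous 25–30 Hz pulse train produced on alternating
egressive/ingressive airstreams, lasting seconds to minutes). `vocsig`
implements the standard analysis chain for quantifying individual
signatures in such calls:

1. **Features** — each call is summarised by its duration, spectral
   centroid, and ten frame-averaged mel-frequency cepstral coefficients
   (MFCC1–10; 30 ms analysis windows for meows, 300 ms for purrs).
2. **Discrimination** — stepwise discriminant function analysis (Wilks' Λ
   selection with F-to-enter/F-to-remove), leave-one-out cross-validated
   classification with priors proportional to group sizes, the chance
   level 100/g %, and an exact one-sided binomial test.
3. **Information** — Beecher's stereotypy index per parameter,
   *H*ₛ = log₂ √((F + n̄ − 1)/n̄) bits, where F is the one-way ANOVA statistic
   for individual identity and n̄ the mean calls per individual; summed over
   the MFCCs it gives the total signature information *H*ₛ and the capacity
   2^*H*ₛ — the number of individuals the call type could encode.
4. **Dispersion** — per-call Euclidean distance to the own-group centroid
   in discriminant signal space, compared across groups by one-way ANOVA
   with partial η² and Tukey post-hoc tests (the within-species
   variability comparison).
5. **Synthesis** — a source–filter generator of meow-like and purr-like
   calls with separately controllable between-individual and
   within-individual variance, so every stage is testable against known
   ground truth without any field recordings.

## Worked example

```python
import vocsig as vs

# 8 synthetic individuals x 15 meows each, known ground truth
spec = vs.CohortSpec(n_individuals=8, calls_per_individual=15,
                     call_type="meow", sample_rate=16_000.0, seed=42)
features = vs.extract_feature_table(vs.generate_cohort(spec))

table = vs.FeatureTable(features, group_field="individual_id")
result = vs.classify_loocv(table)
print(f"correct: {result.overall_correct:.1f}% "
      f"(chance {result.chance_level:.1f}%, p = {result.binomial_p:.2g})")

mfcc_only = vs.FeatureTable(features, [f"mfcc{i}" for i in range(1, 11)],
                            "individual_id")
info = vs.compute_stereotypy(mfcc_only)
print(f"total H_S = {info.total_Hs:.2f} bits -> "
      f"capacity {info.capacity:.1f} individuals")
```

prints

```
correct: 74.2% (chance 12.5%, p = 3.5e-54)
total H_S = 6.53 bits -> capacity 92.2 individuals
```

74.2% of the 120 calls are assigned to the correct individual by
leave-one-out classification — far above the 12.5% chance level for eight
groups (exact binomial p ≈ 10⁻⁵⁴), so these synthetic meows carry a strong
individual signature; the summed stereotypy index says the ten MFCCs carry
about 6.5 bits of identity information under these clean synthetic
conditions.

The same chain runs from the shell:

```bash
vocsig synthesize --n-individuals 8 --calls-per-individual 15 \
    --call-type meow --seed 42 --out cohort/
vocsig extract --wav-dir cohort/ --out features.csv
vocsig discriminate --features features.csv --group-by individual_id
vocsig information --features features.csv
vocsig dispersion --features features.csv --group-by species_id
vocsig run-all --input-mode synthetic --out report/
```

Pre-extracted feature tables (one row per call: labels, duration, spectral
centroid, MFCC1–10; delimiter and header variants are sniffed) are accepted
everywhere via `--features`/`input_mode="feature_csv"`, so published
supplementary tables can be analysed without the raw audio.

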