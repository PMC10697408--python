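# nukaflow

Shared-ASV source tracking for microbial transmission from a fermented
rice-bran bed (*Nukadoko*) to human palm skin.

*Nukadoko* is a Japanese rice-bran bed used to ferment pickles; it is
maintained by stirring with bare hands, which puts a stable, lactic-acid-
bacterium-dominated community in daily contact with the caretaker's skin.
`nukaflow` implements the full analysis used to ask whether bed microbes
settle on the skin and how fast they are shed: 16S ASV feature-table
preprocessing, alpha diversity with rarefaction, the paired shared-ASV
transmission statistic, reference-sequence curation filters, and a simulator
that generates study-shaped data with known ground truth so every stage is
testable without sequencing data.

## The statistic

For a **source** sample (bed) and a **sink** sample (skin) from the same
subject, an ASV *i* is **shared** when its relative abundance exceeds a
threshold *t* (default 1%) in **both** samples:

```
shared(pair) = { i : p_i^source > t  and  p_i^sink > t }
```

The per-pair transmission signal is the sink-weighted shared proportion,

```
S = 100 × Σ_{i ∈ shared} p_i^sink   (percent of skin reads)
```

Pairing follows the study design: during the daily-stirring **contact**
phase (days 0–14, including the pre- and 6-h-post-interaction day-0 samples
"0" and "0′") each skin sample is paired with the same day's bed sample;
during the **no-contact** phase (days 15–29) every skin sample is paired
with the bed sample from the last stirred day (day 14). The simulator models
transfer as a mixture `(1−f)·skin + f·bed` at each stir and shedding as
exponential decay `f_t = f·2^(−Δt/h)` with half-life `h` days.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (outputs land under `results/`):

```
$ python analysis/01_simulate_study.py
wrote 424 features x 57 samples
read depths 13092-41695
subject 1: dominant source ASV at 75.5%

$ python analysis/02_filter_and_composition.py
removed 4 features (33225 reads)
dominant bed genus: Loigolactibacillus at 76.6% mean relative abundance

$ python analysis/04_shared_asv_timecourse.py
39 pairs (0 unpaired)
pre-interaction (day 0) shared proportion: 0.00% max
contact phase: mean 5.40%, range 4.91-5.94%
subject 1: last detection day 15 (true half-life 0.5 d)
```

Reading this: before the first stir no bed ASV exceeds 1% on the skin, so
the shared proportion is zero. Each stir deposits 10% of the bed community;
after a 6-hour shedding step the dominant bed ASV sits at ≈5.4% of skin
reads — shared ASVs are detected at every contact timepoint. Once stirring
stops, the deposit halves every 12 hours: it is still detectable on day 15
and gone by day 18, which is exactly the persistence pattern the pairing
scheme is designed to resolve.

The same stages are available as a CLI (`nukaflow simulate | filter |
diversity | rarefaction | shared-asv | refqc | run`); `nukaflow run
--config config.yaml` executes the full pipeline and writes every table with
a provenance header, byte-identical across reruns of the same config.

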