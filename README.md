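# mitoquant

Quantitation of tandem mCherry-GFP mitophagy/autophagy reporter images.
The tandem tag emits in both channels on neutral structures, but the acidic
lumen of the lysosome quenches GFP, so structures delivered to lysosomes
appear as red-only puncta. `mitoquant` implements the full analysis chain
around that readout, plus a synthetic-image generator that provides
per-object ground truth for validating every stage.

## What it does

- **`mitoquant.synthetic`** — renders two/three-channel scenes
  (mitochondrial networks, mitolysosomes, autophagosomes, autolysosomes,
  immunolabelled cell populations) with PSF blur and Poisson/Gaussian
  noise, each stage togglable, and a ground-truth table recorded before
  degradation. Bit-reproducible for a fixed seed.
- **`mitoquant.detect`** — fine (median) filtering, the `(red+1)/(green+1)`
  ratio image, double-threshold mitolysosome detection (high ratio AND
  high red), and autophagosome/autolysosome classification of
  high-intensity red objects by their mean ratio. Connected components,
  per-object intensity statistics, per-cell attribution by centroid.
- **`mitoquant.tissue`** — immunolabel masks, soma counting within a size
  window, normalization per µm² of staining or per cell body, and
  object-based colocalization (≥1 shared pixel by default, an
  overlap-fraction rule is configurable).
- **`mitoquant.stats`** — trimmed-mean threshold for "mitophagic" cells,
  per-subject averaging, one/two-way ANOVA (type-II SS) with Tukey HSD and
  significance stars, TEM score aggregation (percent containing
  mitochondria, fold vs control), and the two-sample two-sided equality
  sample-size / power calculation.
- **`mitoquant.io` / `mitoquant.pipeline` / `mitoquant.cli`** — OME-TIFF
  read/write with pixel-size calibration, YAML configuration, run
  manifests with config hashes, and a deterministic end-to-end pipeline.

## CLI

```sh
# render synthetic scenes with ground truth
mitoquant simulate --spec scene.yaml --out scenes/ --n-scenes 10 --seed 1

# detect mitolysosomes / classify auto-puncta in a directory of TIFFs
mitoquant quantify-mito --images scenes/ --config cfg.yaml --out results/
mitoquant quantify-auto --images scenes/ --config cfg.yaml --out results/

# object-based colocalization against the label channel
mitoquant coloc --images scenes/ --config cfg.yaml --out results/

# subject summaries + ANOVA/Tukey from a records table
mitoquant stats --in results/records.csv --out results/stats/

# full pipeline: simulate -> detect -> normalize -> stats
mitoquant run --config cfg.yaml --out results/ --seed 1
```

Scene specs and pipeline configs are YAML documents that round-trip
losslessly; write a starting point from Python with
`SceneSpec().to_yaml()` / `PipelineConfig().to_yaml()`.

## Notes

- Detection thresholds are calibration knobs frozen per experiment set;
  the defaults are tuned on the synthetic benchmark (100% exact count
  recovery noise-free, ~2% mean relative count error at SNR 5), not taken
  from any instrument.
- All randomness flows from one top-level seed through named substreams,
  so identical configs give byte-identical outputs.
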