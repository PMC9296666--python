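# atlasdecon

Cross-species cell-type deconvolution of tumour single-cell clusters
against a developmental reference atlas.

## The problem

Brain tumours such as glioblastoma are suspected of hijacking normal
developmental cell states. One way to test this is to ask, for each tumour
cell cluster, which *normal* cell types of a reference atlas its
transcriptome most resembles — including embryonic and juvenile precursor
states that no longer exist in the adult brain. When the reference atlas
comes from another species (e.g. a mouse developmental atlas queried with
human tumour data), the comparison has to pass through an ortholog map.

`atlasdecon` implements this analysis as a reusable, fully tested
pipeline:

1. **Preprocess** — cell QC (minimum detected genes, per-sample
   mitochondrial threshold, high-count doublet rule), sex-gene removal,
   global-scaling log1p normalization, G0/G1 gating on proliferation
   markers, and pseudobulk cluster means.
2. **Signature** — one-vs-rest Wilcoxon rank-sum marker detection with
   expressing-fraction (pct ≥ 0.5) and log-fold-change (ln-LFC ≥ 0.5)
   cutoffs, small-cluster removal, exclusion of cell-cycle / ribosome /
   mitochondrial / apoptosis gene families, ortholog translation, and
   assembly of the signature matrix **S** (genes × cell types, average
   normalized expression).
3. **Deconvolve** — estimate, for each tumour-cluster pseudobulk profile
   *m*, non-negative relative fractions *w* with Σwᵢ = 1 such that
   *m* ≈ **S** *w*, using one of three engines: linear ν-support-vector
   regression (ν ∈ {0.25, 0.5, 0.75}, CIBERSORT-style), non-negative least
   squares, or damped weighted least squares (DWLS).
4. **Report** — call a cell-type *match* when its relative fraction is
   ≥ 0.2, summarize the overlap between match sets, order mixtures by
   hierarchical clustering of their fraction vectors (Newick export), and —
   for synthetic data — score recovery against the known ground truth.
5. **Simulate** — seeded generators for reference atlases with planted
   negative-binomial marker modules, injective ortholog maps, gene-family
   lists and mixtures with known composition, so every stage is verifiable
   by parameter recovery.

## Worked example

```python
import atlasdecon as ad
from atlasdecon.deconvolve import EngineConfig
from atlasdecon.pipeline import PipelineConfig, build_synthetic_signature
from atlasdecon.simulate import sample_ground_truth

cfg = PipelineConfig(
    atlas=ad.AtlasSpec(n_cell_types=8, cells_per_type=60, n_genes=1200,
                       markers_per_type=40, marker_fold_change=8.0, seed=4),
    seed=4,
)
signature, _, _ = build_synthetic_signature(cfg)
truth = sample_ground_truth(signature.columns, 12, seed=5, n_active=3)
mixtures = ad.generate_tumour_mixtures(signature, truth, noise_sd=0.05, seed=6)

for engine in ("nnls", "nusvr", "dwls"):
    table = ad.deconvolve_all(signature, mixtures, EngineConfig(engine=engine))
    err = (table.fractions - mixtures.truth).abs().to_numpy()
    print(f"{engine:>6}: mean |error| {err.mean():.4f}, max |error| {err.max():.4f}")
```

prints

```
  nnls: mean |error| 0.0027, max |error| 0.0114
 nusvr: mean |error| 0.0046, max |error| 0.0471
  dwls: mean |error| 0.0028, max |error| 0.0132
```

i.e. with 5 % relative noise on the mixtures, all three engines recover
the true mixing fractions to well under one percentage point on average;
at zero noise NNLS and DWLS are exact to machine precision. The
`examples/` directory walks through each capability
(`01_simulate_atlas.py` … `04_match_report.py`), and the `atlasdecon` CLI
(`simulate`, `preprocess`, `signature`, `deconvolve`, `report`,
`pipeline`) chains the same functions over Matrix-Market/TSV files.

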