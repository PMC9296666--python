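"""Deconvolve synthetic tumour mixtures with all three engines.

Mixtures are known convex combinations of signature columns plus 5%
relative Gaussian noise; because the true fractions are known, the mean
absolute error of each engine's estimates measures recovery directly.
"""

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
    print(f"{engine:>6}: mean |error| {err.mean():.4f}, "
          f"max |error| {err.max():.4f}, "
          f"median fit RMSE {table.stats['rmse'].median():.4f}")
# all engines should sit well under 0.05 mean absolute fraction error at
# this noise level; nnls and dwls agree almost exactly at zero noise, and
# nu-SVR trades a little bias for robustness on noisy real mixtures

table = ad.deconvolve_all(signature, mixtures, EngineConfig(engine="nusvr"))
print("\nestimated fractions (first 3 mixtures):")
print(table.fractions.iloc[:, :3].round(3))
print("\nchosen nu per mixture:", table.stats["nu"].tolist()[:6], "...")
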