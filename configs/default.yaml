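# Default run configuration for the enhancement pipeline.
# Every key mirrors a RunConfig field; unknown keys are rejected.

patch_rows: 22            # patch grid rows (220x200 image -> 10x10-pixel patches)
patch_cols: 20            # patch grid columns
neighborhood: 4           # pixel connectivity for the smoothness term: 4 or 8
kappa0: 0.1               # base coupling strength before orientation modulation
hyperplane_dim: 2         # drives the class count Q via the parity branch (2 -> 5)
Q: null                   # explicit class count; null = derive from hyperplane_dim
alpha: 0.7                # blend of stretched vs original intensities in [0, 1]
max_sweeps: 100           # relaxation sweep budget per patch
seed: 0                   # master seed for all stochastic choices
smoothness_sign: potts    # "potts" rewards label agreement, "paper" penalizes it
recompute_orientation: false  # second outer pass with refreshed prototypes
prototype_method: quantile    # "quantile" or "kmeans" prototype initialization
window_shape: gaussian    # structure-tensor smoothing window: gaussian or box
window_size: 5            # window side length (odd)
window_sigma: 1.0         # gaussian window sigma
gradient_operator: central    # "central" differences or "sobel"
quantize_output: true     # round the enhanced image to 8-bit levels
log_level: INFO
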