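"""Generate a ground-truthed synthetic cell mixture.

Builds the 12-sample cancer/immune design: a marker-block signature for six
cell types (cancer cells + five immune populations), two pure-tumour
samples, cancer fractions of 30-50% elsewhere, and 5% multiplicative noise.
"""

from mixdecon import MixtureDesign, SignatureDesign, make_dataset

ds = make_dataset(
    SignatureDesign(n_genes=500, markers_per_type=10, marker_fold=10.0,
                    spillover=0.1, seed=1),
    MixtureDesign(proportion_mode="gse64385_like", noise_cv=0.05, seed=2),
)

print(f"bulk B:       {ds.B.shape[0]} genes x {ds.B.shape[1]} samples")
print(f"signature S:  {ds.S_true.shape[0]} genes x {ds.S_true.shape[1]} cell types")
print(f"proportions P: {ds.P_true.shape[0]} cell types x {ds.P_true.shape[1]} samples")
print()
print("true proportions of the first four samples (columns sum to 1;")
print("S01/S02 are pure cancer-cell samples):")
print(ds.P_true.data.iloc[:, :4].round(3).to_string())
print()
print("markers planted for cancer cells:", ds.marker_truth["CC"][:5], "...")
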