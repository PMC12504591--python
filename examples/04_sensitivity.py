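"""Which inputs drive the silvoarable carbon stock? Sobol indices.

Runs a variance-based global sensitivity analysis of the model under the
package's surrogate parameter ranges: scrambled-Sobol Saltelli sampling,
Saltelli-2010 first-order and Jansen total-order estimators.
"""

from silvocarbon import run_sobol

res = run_sobol(base_n=4096, seed=7)
print(f"{res.base_n} base points x (12 + 2) = "
      f"{res.base_n * 14} model evaluations")
print(f"output variance: {res.variance:.2f} (t C/ha)^2\n")
print(res.to_frame().round(4).to_string(index=False))

print(f"\nranking by total-order index: {' > '.join(res.ranking()[:4])} > ...")
print("Soil organic carbon under the tree rows (SOCt) dominates the")
print("variance; mulberry density (TD) is a clear second. S1 ~ ST for")
print("every input, so the model is effectively additive over these ranges.")
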