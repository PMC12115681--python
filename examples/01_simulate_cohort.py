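"""Simulate a phantom cohort: NIfTI volumes plus an ADHD-200-dialect CSV.

Generates 4 + 4 subjects (half with the anterior class effect), writes one
compressed NIfTI per subject and a phenotype table whose rows include a
few deliberately invalid entries, then shows what the demographic filters
reject.
"""

from pathlib import Path

from slicemap import PhantomSpec, make_cohort, prepare_phenotype

out = Path("scratch/example_cohort")
spec = PhantomSpec(n_per_class=4, native_slices=60, in_plane=96,
                   effect_size=8.0, noise_sd=0.05, invalid_fraction=0.25, seed=42)
table = make_cohort(spec, out)
print(f"wrote {len(table)} subjects to {out}")
print(table[["Subject_ID", "DX", "Age", "Full4_IQ", "Secondary_DX"]].to_string(index=False))

clean, audit = prepare_phenotype(out / "phenotype.csv")
print(f"\n{len(clean)} subjects survive QC + validation; {len(audit)} excluded:")
for sid, stage, reason in audit:
    print(f"  {sid}: {stage} -> {reason}")
# The surviving table carries the binarised diagnosis (0 typical, 1 any
# ADHD subtype) plus the five raw personal attributes used for fusion.
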