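"""OPLS-DA screening of a plasma metabolite matrix.

Metabolites are called differential when VIP > 1 (above-average
contribution to the class-predictive component) and the Student's t-test
BH-adjusted q < 0.05 — the joint rule used for both plasma and tissue
untargeted panels.
"""

import keloidomics as k

tab, meta, truth = k.generate_microbiome(seed=4)
plasma = k.generate_metabolome(meta, truth, n_mets=780, n_diff=20, n_cross=10,
                               compartment="plasma", seed=4)
calls = k.differential.oplsda_vip(plasma, meta, n_ortho=1,
                                  vip_cut=1.0, fdr_cut=0.05)
sig = calls.table[calls.table["significant"]]
print(f"{len(sig)} of {len(calls.table)} metabolites called "
      f"(VIP > 1 and q < 0.05)")
print(f"mean(VIP^2) = {(calls.table['vip']**2).mean():.6f} "
      "(the VIP normalization identity)")

planted = set(truth.diff_metabolite_ids('plasma'))
print(f"planted metabolites recovered: {len(planted & set(sig.index))}"
      f"/{len(planted)}")

# targeted quantification against a linear standard curve
conc, flags = k.differential.standard_curve_quantify(
    [(0, 10), (5, 60), (10, 110)], [35.0, 150.0])
print(f"standard curve: response 35 -> {conc[0]:.2f} units; "
      f"response 150 -> {conc[1]:.2f} units"
      f"{' (extrapolated beyond calibration!)' if flags[1] else ''}")
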