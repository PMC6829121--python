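# Default experiment configuration.
#
# The architecture grid is the standard 42-combination factorial:
# h2_sq x rho_g x rho_r = 2 x 3 x 7 at focal heritability 0.2 (add 0.6 to
# h1_sq for the high-heritability variant). The synthetic GRM emulates a
# line-breeding program: 40 families of 10 with mean within-family
# relatedness ~0.4.
seed: 20190911
reps: 200
designs: [naive]

grid:
  h1_sq: [0.2]
  h2_sq: [0.2, 0.6]
  rho_g: [0.0, 0.3, 0.6]
  rho_r: [-0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6]

grm:
  path: null          # set to a dense delimited GRM file to use real data
  n_lines: 400
  n_families: 40
  n_markers: 2000
  fst: 0.25

# test-set fraction per design (parametric needs half the data for the
# validation-side variance-component fit)
test_fractions:
  naive: 0.1
  parametric: 0.5
  cv2star_clone: 0.1
  cv2star_relative: 0.1

correction: h          # divide phenotype-validated correlations by sqrt(h1_sq); "h2" divides by h1_sq
include_ebv: false     # also score against full-data EBVs (demonstrates their upward bias)
drop_nonconverged: false
n_jobs: 1
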