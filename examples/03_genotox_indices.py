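"""CBMN and comet-assay index calculus on scored slides.

A CBMN slide records how many cells carried 1-4 nuclei after a
cytochalasin-B cytokinesis block, plus micronuclei found among
binucleated cells; a comet record carries per-cell electrophoresis
measurements.  The indices below quantify cytostasis (RI, CBPI) and DNA
damage (MN frequency, Tail Moment, Olive Tail Moment).
"""

from ozotox import (
    CometCellRecord,
    MNScoreRecord,
    cbpi,
    compare_groups,
    mn_frequency,
    olive_tail_moment,
    replication_index,
    tail_moment,
)

treated = MNScoreRecord(
    slide_id="oz-48h", cell_line="A549", condition="ozone", time_h=48.0,
    n_mono=550, n_bi=400, n_tri=30, n_tetra=20,
    n_total=1000, n_bn_scored=1000, n_mn=25,
)
control = MNScoreRecord(
    slide_id="ct-48h", cell_line="A549", condition="control", time_h=48.0,
    n_mono=400, n_bi=500, n_tri=60, n_tetra=40,
    n_total=1000, n_bn_scored=1000, n_mn=12,
)

print("RI   = %.2f %%  (below 100: ozone-induced cytostasis)"
      % replication_index(treated, control))
print("CBPI = %.2f (treated) vs %.2f (control)" % (cbpi(treated), cbpi(control)))
print("MN   = %.1f vs %.1f per 1000 binucleated cells"
      % (mn_frequency(treated), mn_frequency(control)))

cell = CometCellRecord(
    cell_id="c1", cell_line="A549", condition="ozone", time_h=48.0,
    tail_dna_pct=50.0, tail_length=100.0, centroid_distance=8.0,
)
print("Tail Moment       = %.1f  (50%% tail DNA x 100 um tail / 100)"
      % tail_moment(cell))
print("Olive Tail Moment = %.1f  (50%% tail DNA x 8 um centroid gap / 100)"
      % olive_tail_moment(cell))

# Small-sample comparison: Mann-Whitney with combined n <= 10 uses the
# exact permutation distribution of the rank sum.
res = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], test="mann_whitney")
print("exact Mann-Whitney on {1,2,3} vs {10,11,12}: p = %.3f %s"
      % (res.p_value, res.stars or "(ns)"))
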