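"""Show how artifact filtering changes the group-level decomposition.

Simulates a 29-subject cohort of component spatial maps on a 1-D voxel
lattice: four shared network templates per subject plus artifact maps
(a strong boundary pattern and pure noise).  A secondary ICA is run on the
temporally concatenated maps twice — once on everything, once keeping only
the RSN candidates — and each run's group maps are matched to the planted
templates by absolute spatial correlation.
"""

import numpy as np

import icfilter as icf
from icfilter.group_ica import concatenate_maps, match_maps, secondary_ica

sets, labels, templates = icf.simulate_map_cohort(
    n_subjects=29, n_components=10, n_voxels=400, n_templates=4,
    noise_sd=0.3, seed=17,
)

for name, filt in (("unfiltered", None), ("filtered", labels)):
    data, provenance = concatenate_maps(sets, filt)
    result = secondary_ica(data, q=4, seed=3)
    _, corrs = match_maps(result.group_maps, templates)
    print(f"{name:>10}: concatenated rows = {data.shape[0]:4d}, "
          f"matched template |r| = {np.round(corrs, 3)} "
          f"(mean {corrs.mean():.3f})")

print("\nWith artifact maps left in, the secondary ICA spends components on "
      "artifact structure and recovers the planted networks poorly; after "
      "filtering, every template is recovered almost exactly.")
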