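"""Synaptic maturation read-outs: puncta densities, EM areal density and
dendritic spine density.

Simulates a GFP/Synapsin/Homer1 confocal plane with compartment-dependent
puncta densities (Homer1 sparser inside the graft, the immature-synapse
pattern), detects spots with difference-of-Gaussians, and computes densities
on the human-cell mask; then reproduces the published EM worked examples and
a spine-density table.
"""

import numpy as np

import graftquant as gq

params = gq.PunctaSimParams(
    height_px=600,
    width_px=600,
    pixel_size_um=0.25,
    graft_thickness_um=100.0,
    seed=3,
)
stack, truth = gq.simulate_puncta_image(params)
human = gq.human_cell_mask(stack.channel("GFP")[0], threshold=5000.0)
graft = np.zeros((600, 600), bool)
graft[: truth.graft_rows] = True
comp = gq.split_graft_compartments(graft, ~graft, params.pixel_size_um, 50.0)

print("puncta per um^2 of compartment ∩ human-cell mask (truth in brackets):")
for channel in ("Synapsin", "Homer1"):
    spots = gq.detect_puncta(
        stack.channel(channel)[0], sigma_um=0.3, pixel_size_um=0.25,
        min_quality=200.0,
    )
    for region in ("mouse_cortex", "below50", "above50"):
        rec = gq.puncta_density(
            spots, comp.mask(region)[0], human, params.pixel_size_um,
            compartment=region, channel=channel,
        )
        want = params.puncta_density_per_um2[channel][region]
        print(
            f"  {channel:9s} {region:12s} {rec.density_per_um2:.3f} "
            f"({rec.n_spots} spots / {rec.area_um2:.0f} um^2)  [{want:.2f}]"
        )

print("\nEM areal density, profiles per 100 um^2 (raw -> reported integer):")
for n, depth in ((12, "mid-graft, ~230 um deep"), (53, "host cortex, ~600 um")):
    raw, reported = gq.em_areal_density(n, 258.0)
    print(f"  {n} profiles in a 258 um^2 field ({depth}): {raw:.2f} -> {reported}")

counts = [3, 11, 9, 14, 6]
lengths = [35.0, 80.0, 72.0, 110.0, 54.0]
per, mean = gq.spine_density(counts, lengths)
print("\nspine density per traced dendrite (spines/um):", np.round(per, 3))
print(f"mean spine density: {mean:.3f} spines/um")
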