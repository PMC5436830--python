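"""Detect hydrogen bonds in a synthetic binding site and score the network.

Builds a small wild-type-like ATP site with planted donor-H···acceptor
geometries, detects bonds under the 2.7 Å / 30° criteria, and converts the
network to kcal/mol with the exponential distance-energy relation."""

from mgatp.energetics import frame_ehb
from mgatp.hbonds import helix_rest_hbonds, protein_atp_hbonds
from mgatp.synthetic import build_site_trajectory, default_site_config

trajectory, truth = build_site_trajectory(
    default_site_config("wild_type", n_frames=5, jitter_sigma=0.02, seed=1)
)
frame = trajectory.frames[0]

protein_atp = protein_atp_hbonds(frame)
helix = helix_rest_hbonds(frame)

print(f"protein-ATP hydrogen bonds : {len(protein_atp)} (planted {truth.n_protein_atp})")
print(f"helix-to-rest hydrogen bonds: {len(helix)} (planted {truth.n_helix})")
for record in protein_atp[:3]:
    print(f"  {record.donor.residue_name}{record.donor.residue_number}:"
          f"{record.donor.name} -> {record.acceptor.name}  "
          f"d(H..A) = {record.d_ha:.2f} A, deviation = {record.angle_deviation:.1f} deg")
print(f"E_HB(protein-ATP) = {frame_ehb(protein_atp):7.1f} kcal/mol")
print(f"E_HB(helix)       = {frame_ehb(helix):7.1f} kcal/mol")
print("Each bond contributes 502e3*exp(-3.6 d) kJ/mol; the sums above are the")
print("network magnitudes in kcal/mol for this single frame.")
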