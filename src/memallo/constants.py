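"""Named analysis defaults, collected in one place.

These are the knobs every stage exposes; each CLI flag and config field
defaults to the value here.
"""

#: Occupancy grid resolution (Å per voxel).
GRID_SPACING = 1.0

#: Minimum fraction of frames a voxel must be occupied to be reported.
MIN_OCCUPANCY = 0.5

#: Protein-proximity cutoff (Å) for the optional occupancy contact mask.
CONTACT_MASK_CUTOFF = 6.0

#: Overlap threshold above which a residue counts as an allosteric hotspot.
OVERLAP_THRESHOLD = 0.6

#: Random force directions per perturbation-scan repeat.
N_DIRECTIONS = 1000

#: Number of independent repeats of the perturbation scan.
N_REPEATS = 5

#: Dual-cutoff contact detection: contact starts below R_ON, ends above R_OFF.
R_ON = 4.75
R_OFF = 7.0

#: Minimum co-occurrence fraction for an edge in the binding-site residue graph.
CO_OCCURRENCE_MIN = 0.5

#: Residence-time flag for long-lived sites (ns); 3 us.
SITE_FLAG_NS = 3000.0

#: Hydrogen bond: donor-heavy-atom to acceptor distance cutoff (Å), inclusive.
HBOND_DISTANCE = 3.5

#: Hydrogen bond: minimum donor-H-acceptor angle (degrees), inclusive.
HBOND_ANGLE = 130.0

#: Hydrophobic contact distance cutoff (Å), inclusive.
HYDROPHOBIC_DISTANCE = 4.5

#: Pore profile slab thickness (Å) and search-cylinder radius (Å).
PORE_SLAB = 1.0
PORE_SEARCH_RADIUS = 15.0

#: Fewest events for which the survival fit is attempted (below: mean duration).
MIN_EVENTS_FOR_FIT = 5

#: Events separated by at most this many frames are stitched together.
GAP_STITCH_FRAMES = 1

#: van der Waals radii (Å), Bondi (1964) values for the elements that occur
#: in protein/lipid systems; used by the pore profiler.
VDW_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Na": 2.27,
    "X": 1.70,
}
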