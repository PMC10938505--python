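"""Frozen idealized A-form-like nucleotide templates (helix frame).

Generated once from idealized bond lengths/angles, a C3'-endo sugar
pucker and near-A-form backbone torsions tuned so that the emergent
helix stacks cleanly and is clash-free.  Do not edit by hand.
"""

TWIST = 23.066196440935
RISE = 2.557357155360

TEMPLATE_COORDS = {
    "A": {
        "P": (7.036605469809, 10.340748276029, -2.912648146466),
        "OP1": (6.884651601823, 11.783712104234, -2.596435539987),
        "OP2": (7.433752324241, 9.927936665452, -4.282716009817),
        "O5'": (5.666830640586, 9.610403134695, -2.554930532084),
        "C5'": (4.677334389026, 10.256334910515, -1.731966796998),
        "C4'": (5.299142750850, 10.721141483584, -0.436818461701),
        "O4'": (6.292000937048, 9.761696475610, -0.015704214513),
        "C3'": (4.326936463775, 10.870671722208, 0.749966691606),
        "O3'": (3.630448496366, 12.109034116542, 0.670643984237),
        "C2'": (4.911143417673, 9.937526463441, 1.829882622695),
        "O2'": (3.923048264751, 9.233979189524, 2.554629614550),
        "C1'": (5.749885627120, 8.980361459244, 1.003227169060),
        "N9": (4.960249441453, 7.907025119977, 0.387233827298),
        "C8": (4.599389650087, 7.797624904865, -0.932847598026),
        "N7": (3.889673760968, 6.726040592253, -1.195226941618),
        "C5": (3.777566325228, 6.090561040322, 0.033817414522),
        "C6": (3.140740663857, 4.897008019553, 0.430683224885),
        "N6": (2.480349742759, 4.133754773494, -0.450752146377),
        "N1": (3.222397478764, 4.553379376785, 1.733294843554),
        "C2": (3.895594067296, 5.353877992280, 2.570656150516),
        "N3": (4.530146886251, 6.493564082896, 2.310393077838),
        "C4": (4.431400994242, 6.807835450111, 1.011151169769),
    },
    "U": {
        "P": (7.036605469809, 10.340748276029, -2.912648146466),
        "OP1": (6.884651601823, 11.783712104234, -2.596435539987),
        "OP2": (7.433752324241, 9.927936665452, -4.282716009817),
        "O5'": (5.666830640586, 9.610403134695, -2.554930532084),
        "C5'": (4.677334389026, 10.256334910515, -1.731966796998),
        "C4'": (5.299142750850, 10.721141483584, -0.436818461701),
        "O4'": (6.292000937048, 9.761696475610, -0.015704214513),
        "C3'": (4.326936463775, 10.870671722208, 0.749966691606),
        "O3'": (3.630448496366, 12.109034116542, 0.670643984237),
        "C2'": (4.911143417673, 9.937526463441, 1.829882622695),
        "O2'": (3.923048264751, 9.233979189524, 2.554629614550),
        "C1'": (5.749885627120, 8.980361459244, 1.003227169060),
        "N1": (4.960249441453, 7.907025119977, 0.387233827298),
        "C2": (4.501808701137, 6.865007994402, 1.171078990062),
        "O2": (4.726912956555, 6.796154989460, 2.368153481438),
        "N3": (3.774777131452, 5.914370111108, 0.501454628580),
        "C4": (3.463427571291, 5.895111761952, -0.842256032382),
        "O4": (2.801800500300, 4.995726341260, -1.358255532361),
        "C5": (3.974592317735, 7.011033762081, -1.591070755460),
        "C6": (4.687914958128, 7.955263352611, -0.965458184738),
    },
    "G": {
        "P": (7.036605469809, 10.340748276029, -2.912648146466),
        "OP1": (6.884651601823, 11.783712104234, -2.596435539987),
        "OP2": (7.433752324241, 9.927936665452, -4.282716009817),
        "O5'": (5.666830640586, 9.610403134695, -2.554930532084),
        "C5'": (4.677334389026, 10.256334910515, -1.731966796998),
        "C4'": (5.299142750850, 10.721141483584, -0.436818461701),
        "O4'": (6.292000937048, 9.761696475610, -0.015704214513),
        "C3'": (4.326936463775, 10.870671722208, 0.749966691606),
        "O3'": (3.630448496366, 12.109034116542, 0.670643984237),
        "C2'": (4.911143417673, 9.937526463441, 1.829882622695),
        "O2'": (3.923048264751, 9.233979189524, 2.554629614550),
        "C1'": (5.749885627120, 8.980361459244, 1.003227169060),
        "N9": (4.960249441453, 7.907025119977, 0.387233827298),
        "C8": (4.599389650087, 7.797624904865, -0.932847598026),
        "N7": (3.889673760968, 6.726040592253, -1.195226941618),
        "C5": (3.777566325228, 6.090561040322, 0.033817414522),
        "C6": (3.140740663857, 4.897008019553, 0.430683224885),
        "O6": (2.534560937774, 4.196409890708, -0.378395511423),
        "N1": (3.222397478764, 4.553379376785, 1.733294843554),
        "C2": (3.895594067296, 5.353877992280, 2.570656150516),
        "N2": (3.935108258631, 4.950244326409, 3.847808644332),
        "N3": (4.530146886251, 6.493564082896, 2.310393077838),
        "C4": (4.431400994242, 6.807835450111, 1.011151169769),
    },
    "C": {
        "P": (7.036605469809, 10.340748276029, -2.912648146466),
        "OP1": (6.884651601823, 11.783712104234, -2.596435539987),
        "OP2": (7.433752324241, 9.927936665452, -4.282716009817),
        "O5'": (5.666830640586, 9.610403134695, -2.554930532084),
        "C5'": (4.677334389026, 10.256334910515, -1.731966796998),
        "C4'": (5.299142750850, 10.721141483584, -0.436818461701),
        "O4'": (6.292000937048, 9.761696475610, -0.015704214513),
        "C3'": (4.326936463775, 10.870671722208, 0.749966691606),
        "O3'": (3.630448496366, 12.109034116542, 0.670643984237),
        "C2'": (4.911143417673, 9.937526463441, 1.829882622695),
        "O2'": (3.923048264751, 9.233979189524, 2.554629614550),
        "C1'": (5.749885627120, 8.980361459244, 1.003227169060),
        "N1": (4.960249441453, 7.907025119977, 0.387233827298),
        "C2": (4.501808701137, 6.865007994402, 1.171078990062),
        "O2": (4.726912956555, 6.796154989460, 2.368153481438),
        "N3": (3.774777131452, 5.914370111108, 0.501454628580),
        "C4": (3.463427571291, 5.895111761952, -0.842256032382),
        "N4": (2.742630599642, 4.915293498760, -1.404401829107),
        "C5": (3.974592317735, 7.011033762081, -1.591070755460),
        "C6": (4.687914958128, 7.955263352611, -0.965458184738),
    },
}
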