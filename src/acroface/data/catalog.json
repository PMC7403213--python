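{
  "comment": "Default 58-parameter craniofacial measurement catalog. Operand assignments follow standard soft-tissue anthropometry conventions and are editable here without code changes. Point specs are landmark keys or {\"mid\": [k1, k2]}; index operands are {\"measurement\": id}, {\"distance\": [a, b]} or {\"sum\": [refs]}.",
  "entries": [
    {"id": "MFH", "name": "Morphological face height", "kind": "linear", "units": "mm", "points": ["n", "gn"]},
    {"id": "LFH", "name": "Lower facial height", "kind": "linear", "units": "mm", "points": ["sn", "gn"]},
    {"id": "FB", "name": "Face breadth", "kind": "linear", "units": "mm", "points": ["zy_l", "zy_r"]},
    {"id": "BB", "name": "Bigonial breadth", "kind": "linear", "units": "mm", "points": ["go_l", "go_r"]},
    {"id": "BtW", "name": "Bitragal width", "kind": "linear", "units": "mm", "points": ["tr_l", "tr_r"]},
    {"id": "BnW", "name": "Binocular width", "kind": "linear", "units": "mm", "points": ["ec_l", "ec_r"]},
    {"id": "ICW", "name": "Intercanthal width", "kind": "linear", "units": "mm", "points": ["en_l", "en_r"]},
    {"id": "OW", "name": "Ocular width", "kind": "linear_avg", "units": "mm", "pairs": [["en_l", "ec_l"], ["en_r", "ec_r"]]},
    {"id": "NH", "name": "Nose height", "kind": "linear", "units": "mm", "points": ["n", "sn"]},
    {"id": "NL", "name": "Nose length", "kind": "linear", "units": "mm", "points": ["n", "prn"]},
    {"id": "NW", "name": "Nose width", "kind": "linear", "units": "mm", "points": ["al_l", "al_r"]},
    {"id": "ND", "name": "Nasal depth", "kind": "linear", "units": "mm", "points": ["sn", "prn"]},
    {"id": "MW", "name": "Mouth width", "kind": "linear", "units": "mm", "points": ["ch_l", "ch_r"]},
    {"id": "TULH", "name": "Total upper lip height", "kind": "linear", "units": "mm", "points": ["sn", "sto"]},
    {"id": "PL", "name": "Philtrum length", "kind": "linear", "units": "mm", "points": ["sn", "ls"]},
    {"id": "UVH", "name": "Upper vermilion height", "kind": "linear", "units": "mm", "points": ["ls", "sto"]},
    {"id": "LVH", "name": "Lower vermilion height", "kind": "linear", "units": "mm", "points": ["sto", "li"]},
    {"id": "UVCL", "name": "Upper vermilion curve length", "kind": "curve", "units": "mm", "chain": ["ls", "sto"], "mesh_window": ["ls", "sto"]},
    {"id": "LVCL", "name": "Lower vermilion curve length", "kind": "curve", "units": "mm", "chain": ["sto", "li"], "mesh_window": ["sto", "li"]},
    {"id": "MCL", "name": "Mandible curve length", "kind": "curve", "units": "mm", "chain": ["go_l", "gn", "go_r"]},
    {"id": "FLI", "name": "Facial length index", "kind": "index", "units": "index", "numerator": {"measurement": "MFH"}, "denominator": {"measurement": "FB"}},
    {"id": "MFI", "name": "Mandibulo facial index", "kind": "index", "units": "index", "numerator": {"measurement": "BB"}, "denominator": {"measurement": "FB"}},
    {"id": "II", "name": "Intercanthal index", "kind": "index", "units": "index", "numerator": {"measurement": "ICW"}, "denominator": {"measurement": "BnW"}},
    {"id": "NLI", "name": "Nasal length index", "kind": "index", "units": "index", "numerator": {"measurement": "NH"}, "denominator": {"measurement": "MFH"}},
    {"id": "NWI", "name": "Nasal width index", "kind": "index", "units": "index", "numerator": {"measurement": "NW"}, "denominator": {"measurement": "NH"}},
    {"id": "LI", "name": "Labial index", "kind": "index", "units": "index", "numerator": {"sum": [{"measurement": "UVH"}, {"measurement": "LVH"}]}, "denominator": {"measurement": "MW"}},
    {"id": "ULLI", "name": "Upper lip length index", "kind": "index", "units": "index", "numerator": {"measurement": "TULH"}, "denominator": {"measurement": "LFH"}},
    {"id": "LLLI", "name": "Lower lip length index", "kind": "index", "units": "index", "numerator": {"distance": ["sto", "sm"]}, "denominator": {"measurement": "LFH"}},
    {"id": "CHI", "name": "Chin height index", "kind": "index", "units": "index", "numerator": {"distance": ["sm", "gn"]}, "denominator": {"measurement": "LFH"}},
    {"id": "ICI", "name": "Iridio chelial index", "kind": "index", "units": "index", "numerator": {"measurement": "MW"}, "denominator": {"distance": ["im_l", "im_r"]}},
    {"id": "EAI", "name": "Endocanthal alar index", "kind": "index", "units": "index", "numerator": {"measurement": "ICW"}, "denominator": {"measurement": "NW"}},
    {"id": "ACI", "name": "Alar chelial index", "kind": "index", "units": "index", "numerator": {"measurement": "NW"}, "denominator": {"measurement": "MW"}},
    {"id": "LOTI", "name": "Labio orbital triangle index", "kind": "triangle_index", "units": "index", "apex": "ls", "base": ["or_l", "or_r"]},
    {"id": "NOT", "name": "Naso orbital triangle", "kind": "triangle_index", "units": "index", "apex": "sn", "base": ["or_l", "or_r"]},
    {"id": "NCT", "name": "Naso chelial triangle", "kind": "triangle_index", "units": "index", "apex": "sn", "base": ["ch_l", "ch_r"]},
    {"id": "SoD", "name": "Supraorbital depth", "kind": "linear", "units": "mm", "points": ["g", {"mid": ["tr_l", "tr_r"]}]},
    {"id": "UFD", "name": "Upper facial depth", "kind": "linear", "units": "mm", "points": ["n", {"mid": ["tr_l", "tr_r"]}]},
    {"id": "OTD", "name": "Orbito tragial depth", "kind": "linear", "units": "mm", "points": [{"mid": ["or_l", "or_r"]}, {"mid": ["tr_l", "tr_r"]}]},
    {"id": "LTD", "name": "Labio tragial depth", "kind": "linear", "units": "mm", "points": ["ls", {"mid": ["tr_l", "tr_r"]}]},
    {"id": "MFD", "name": "Middle facial depth", "kind": "linear", "units": "mm", "points": ["sn", {"mid": ["tr_l", "tr_r"]}]},
    {"id": "SD", "name": "Sublabial depth", "kind": "linear", "units": "mm", "points": ["sm", {"mid": ["tr_l", "tr_r"]}]},
    {"id": "LFD", "name": "Lower facial depth", "kind": "linear", "units": "mm", "points": ["pg", {"mid": ["tr_l", "tr_r"]}]},
    {"id": "GTD", "name": "Gonion tragial distance", "kind": "linear_avg", "units": "mm", "pairs": [["go_l", "tr_l"], ["go_r", "tr_r"]]},
    {"id": "GGD", "name": "Gonion gnathion distance", "kind": "linear_avg", "units": "mm", "pairs": [["go_l", "gn"], ["go_r", "gn"]]},
    {"id": "LSEPD", "name": "Labiale superius Esthetic plane distance", "kind": "plane_distance", "units": "mm", "point": "ls", "plane": "esthetic"},
    {"id": "LIEPD", "name": "Labiale inferius Esthetic plane distance", "kind": "plane_distance", "units": "mm", "point": "li", "plane": "esthetic"},
    {"id": "LIE_LSE", "name": "Labiale inferius to E distance minus Labiale superius to E distance", "kind": "derived_difference", "units": "mm", "minuend": "LIEPD", "subtrahend": "LSEPD"},
    {"id": "GTVLD", "name": "Glabella TVL distance", "kind": "plane_distance", "units": "mm", "point": "g", "plane": "TVL"},
    {"id": "PrTVLD", "name": "Pronasale TVL distance", "kind": "plane_distance", "units": "mm", "point": "prn", "plane": "TVL"},
    {"id": "PoTVLD", "name": "Pogonion TVL distance", "kind": "plane_distance", "units": "mm", "point": "pg", "plane": "TVL"},
    {"id": "NFrA", "name": "Nasofrontal angle", "kind": "angle", "units": "degree", "points": ["g", "n", "prn"]},
    {"id": "NmA", "name": "Nasomental angle", "kind": "angle", "units": "degree", "points": ["n", "prn", "pg"]},
    {"id": "NFA", "name": "Naso facial angle", "kind": "angle", "units": "degree", "points": ["prn", "n", "pg"]},
    {"id": "CLA", "name": "Columella labial angle", "kind": "angle", "units": "degree", "points": ["prn", "sn", "ls"]},
    {"id": "FA", "name": "Facial angle", "kind": "angle", "units": "degree", "points": ["g", "sn", "pg"]},
    {"id": "PTGP", "name": "Pass transglabellar plane", "kind": "semi_perimeter", "units": "mm", "level": "transglabellar"},
    {"id": "PMFP", "name": "Pass midfacial plane", "kind": "semi_perimeter", "units": "mm", "level": "midfacial"},
    {"id": "PTNP", "name": "Pass transverse nasal plane", "kind": "semi_perimeter", "units": "mm", "level": "transverse_nasal"}
  ]
}
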