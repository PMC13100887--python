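# Named movement hypotheses: class -> resistance (>=1) or absolute barrier.
# EMP holds the literature-derived empirical values; NULL is uniform
# resistance (isolation by distance); the remaining entries test single
# landcover groups as barriers (BAR, 100 vs 1) or corridors (COR, 1 vs 100).
# Buildings and waterbodies are always absolute barriers.
'NULL':
  resistance:
    Path: 1
    Railways: 1
    Small street: 1
    Highways: 1
    Large street: 1
    Linear Water: 1
    Wetland: 1
    Impervious: 1
    Woodland: 1
    Lawn: 1
    Amenity: 1
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 1
    Private Garden: 1
    Unclassified: 1
  barriers:
  - Buildings
  - Waterbodies
EMP:
  resistance:
    Path: 14
    Railways: 100
    Small street: 8
    Highways: 100
    Large street: 100
    Linear Water: 100
    Wetland: 100
    Impervious: 13
    Woodland: 100
    Lawn: 5
    Amenity: 6
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 100
    Private Garden: 1
    Unclassified: 15
  barriers:
  - Buildings
  - Waterbodies
RAILBAR:
  resistance:
    Path: 1
    Railways: 100
    Small street: 1
    Highways: 1
    Large street: 1
    Linear Water: 1
    Wetland: 1
    Impervious: 1
    Woodland: 1
    Lawn: 1
    Amenity: 1
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 1
    Private Garden: 1
    Unclassified: 1
  barriers:
  - Buildings
  - Waterbodies
RAILCOR:
  resistance:
    Path: 100
    Railways: 1
    Small street: 100
    Highways: 100
    Large street: 100
    Linear Water: 100
    Wetland: 100
    Impervious: 100
    Woodland: 100
    Lawn: 100
    Amenity: 100
    Parks and Playspace: 100
    Cemeteries: 100
    Allotments: 100
    Farmland: 100
    Private Garden: 100
    Unclassified: 100
  barriers:
  - Buildings
  - Waterbodies
ROADBAR:
  resistance:
    Path: 1
    Railways: 1
    Small street: 100
    Highways: 100
    Large street: 100
    Linear Water: 1
    Wetland: 1
    Impervious: 1
    Woodland: 1
    Lawn: 1
    Amenity: 1
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 1
    Private Garden: 1
    Unclassified: 1
  barriers:
  - Buildings
  - Waterbodies
GREENCOR:
  resistance:
    Path: 100
    Railways: 100
    Small street: 100
    Highways: 100
    Large street: 100
    Linear Water: 100
    Wetland: 100
    Impervious: 100
    Woodland: 1
    Lawn: 1
    Amenity: 1
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 100
    Private Garden: 1
    Unclassified: 100
  barriers:
  - Buildings
  - Waterbodies
FARMBAR:
  resistance:
    Path: 1
    Railways: 1
    Small street: 1
    Highways: 1
    Large street: 1
    Linear Water: 1
    Wetland: 1
    Impervious: 1
    Woodland: 1
    Lawn: 1
    Amenity: 1
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 100
    Private Garden: 1
    Unclassified: 1
  barriers:
  - Buildings
  - Waterbodies
FARMCOR:
  resistance:
    Path: 100
    Railways: 100
    Small street: 100
    Highways: 100
    Large street: 100
    Linear Water: 100
    Wetland: 100
    Impervious: 100
    Woodland: 100
    Lawn: 100
    Amenity: 100
    Parks and Playspace: 100
    Cemeteries: 100
    Allotments: 100
    Farmland: 1
    Private Garden: 100
    Unclassified: 100
  barriers:
  - Buildings
  - Waterbodies
WATERBAR:
  resistance:
    Path: 1
    Railways: 1
    Small street: 1
    Highways: 1
    Large street: 1
    Linear Water: 100
    Wetland: 100
    Impervious: 1
    Woodland: 1
    Lawn: 1
    Amenity: 1
    Parks and Playspace: 1
    Cemeteries: 1
    Allotments: 1
    Farmland: 1
    Private Garden: 1
    Unclassified: 1
  barriers:
  - Buildings
  - Waterbodies
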