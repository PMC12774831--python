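bases:
- name: Consequence
  kind: categorical
  categories:
  - CS
  - SG
  - SL
  - NS
  - SN
  - S
  - U5
  - U3
  - NC
  - I
  - UP
  - DN
  - IG
  - O
  default: IG
  missing_indicator: false
  other_bucket: null
- name: oAA
  kind: categorical
  categories:
  - A
  - C
  - D
  - E
  - F
  - G
  - H
  - I
  - K
  - L
  - M
  - N
  - P
  - Q
  - R
  - S
  - T
  - V
  - W
  - Y
  - '*'
  default: null
  missing_indicator: false
  other_bucket: null
- name: nAA
  kind: categorical
  categories:
  - A
  - C
  - D
  - E
  - F
  - G
  - H
  - I
  - K
  - L
  - M
  - N
  - P
  - Q
  - R
  - S
  - T
  - V
  - W
  - Y
  - '*'
  default: null
  missing_indicator: false
  other_bucket: null
- name: ChromatinBG3
  kind: categorical
  categories:
  - '1'
  - '2'
  - '3'
  - '4'
  - '5'
  - '6'
  - '7'
  - '8'
  - '9'
  default: '9'
  missing_indicator: false
  other_bucket: null
- name: ChromatinS2
  kind: categorical
  categories:
  - '1'
  - '2'
  - '3'
  - '4'
  - '5'
  - '6'
  - '7'
  - '8'
  - '9'
  default: '9'
  missing_indicator: false
  other_bucket: null
- name: CDSpos
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: true
  other_bucket: null
- name: relCDSpos
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: protPos
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: true
  other_bucket: null
- name: relProtPos
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: Grantham
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: true
  other_bucket: null
- name: PhyloP
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: PhyloP124
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: PhyloP_all
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: PhastCons
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: PhastCons124
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: GerpRS_all
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: GERPN_all
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: MGW
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: Roll
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: HelT
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: ProT
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: EP
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: ReMapDensity
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: CDSdist
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: GC
  kind: numeric
  categories: []
  default: 0.0
  missing_indicator: false
  other_bucket: null
- name: rep_DNA
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_LINE
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_LTR
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_LowComplexity
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_RollingCircle
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_Satellite
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_Simple
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: rep_RNA
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: miRNA
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: TFBS
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: CRM
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: pCRM
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
- name: CDS
  kind: indicator
  categories: []
  default: 0
  missing_indicator: false
  other_bucket: null
combinations:
- categorical: Consequence
  numerics:
  - CDSpos
- categorical: Consequence
  numerics:
  - relCDSpos
- categorical: Consequence
  numerics:
  - protPos
- categorical: Consequence
  numerics:
  - relProtPos
- categorical: Consequence
  numerics:
  - Grantham
- categorical: Consequence
  numerics:
  - PhyloP
- categorical: Consequence
  numerics:
  - PhyloP124
- categorical: Consequence
  numerics:
  - PhyloP_all
- categorical: Consequence
  numerics:
  - PhastCons
- categorical: Consequence
  numerics:
  - PhastCons124
- categorical: Consequence
  numerics:
  - GerpRS_all
- categorical: Consequence
  numerics:
  - GERPN_all
- categorical: Consequence
  numerics:
  - MGW
- categorical: Consequence
  numerics:
  - Roll
- categorical: Consequence
  numerics:
  - HelT
- categorical: Consequence
  numerics:
  - ProT
- categorical: Consequence
  numerics:
  - EP
- categorical: Consequence
  numerics:
  - ReMapDensity
- categorical: Consequence
  numerics:
  - CDSdist
- categorical: Consequence
  numerics:
  - GC
- categorical: Consequence
  numerics:
  - relCDSpos
  - PhyloP
- categorical: Consequence
  numerics:
  - relCDSpos
  - PhyloP124
- categorical: Consequence
  numerics:
  - relCDSpos
  - PhyloP_all
- categorical: Consequence
  numerics:
  - relCDSpos
  - PhastCons
- categorical: Consequence
  numerics:
  - relCDSpos
  - PhastCons124
- categorical: Consequence
  numerics:
  - relCDSpos
  - GerpRS_all
- categorical: Consequence
  numerics:
  - relCDSpos
  - GERPN_all
- categorical: Consequence
  numerics:
  - relProtPos
  - PhyloP
- categorical: Consequence
  numerics:
  - relProtPos
  - PhastCons
- categorical: Consequence
  numerics:
  - Grantham
  - PhyloP
- categorical: Consequence
  numerics:
  - CDSdist
  - PhyloP
- categorical: oAA
  numerics:
  - Grantham
- categorical: oAA
  numerics:
  - relProtPos
- categorical: nAA
  numerics:
  - Grantham
- categorical: nAA
  numerics:
  - relProtPos
- categorical: ChromatinBG3
  numerics:
  - PhyloP
- categorical: ChromatinBG3
  numerics:
  - PhastCons
- categorical: ChromatinBG3
  numerics:
  - GC
- categorical: ChromatinS2
  numerics:
  - PhyloP
- categorical: ChromatinS2
  numerics:
  - PhastCons
- categorical: ChromatinS2
  numerics:
  - GC
- categorical: ChromatinBG3
  numerics:
  - ReMapDensity
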