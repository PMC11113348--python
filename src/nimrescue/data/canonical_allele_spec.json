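{
 "alleles": {
  "6HDZ635": [
   "146",
   "150",
   "154"
  ],
  "6HDZ700": [
   "156",
   "160"
  ],
  "6HDZ89": [
   "136",
   "140"
  ],
  "FCA105": [
   "106",
   "110",
   "114",
   "118"
  ],
  "FCA126": [
   "116",
   "120",
   "124",
   "128"
  ],
  "FCA279": [
   "126",
   "130",
   "134",
   "138"
  ],
  "FCA441": [
   "166",
   "170",
   "174"
  ],
  "FCA90": [
   "96",
   "100",
   "104",
   "108",
   "112"
  ]
 },
 "freqs": {
  "captive_oman": {
   "6HDZ635": {
    "146": 0.08322783248384116,
    "150": 0.586083902777053,
    "154": 0.33068826473910595
   },
   "6HDZ700": {
    "156": 0.5440137405115303,
    "160": 0.4559862594884697
   },
   "6HDZ89": {
    "136": 0.3501965912791639,
    "140": 0.6498034087208361
   },
   "FCA105": {
    "106": 0.2519770086027912,
    "110": 0.4359359751514935,
    "114": 0.09756616045038198,
    "118": 0.2145208557953333
   },
   "FCA126": {
    "116": 0.0,
    "120": 0.4842091731269605,
    "124": 0.3229538060227157,
    "128": 0.19283702085032392
   },
   "FCA279": {
    "126": 0.4551030527685347,
    "130": 0.5060100389523158,
    "134": 0.0,
    "138": 0.038886908279149486
   },
   "FCA441": {
    "166": 0.0,
    "170": 0.43041491570325036,
    "174": 0.5695850842967497
   },
   "FCA90": {
    "100": 0.18136498264315168,
    "104": 0.26223979931942204,
    "108": 0.13016186234278887,
    "112": 0.42623335569463744,
    "96": 0.0
   }
  },
  "captive_yemen": {
   "6HDZ635": {
    "146": 0.6283477692125169,
    "150": 0.19838813548819342,
    "154": 0.17326409529928974
   },
   "6HDZ700": {
    "156": 0.08380880604610161,
    "160": 0.9161911939538984
   },
   "6HDZ89": {
    "136": 0.27579100226890446,
    "140": 0.7242089977310956
   },
   "FCA105": {
    "106": 0.17769619091220543,
    "110": 0.22488552272306436,
    "114": 0.3975565982398039,
    "118": 0.19986168812492627
   },
   "FCA126": {
    "116": 0.0,
    "120": 0.44126621857933457,
    "124": 0.5150909711560793,
    "128": 0.04364281026458624
   },
   "FCA279": {
    "126": 0.4599501685726016,
    "130": 0.09001175205346452,
    "134": 0.0,
    "138": 0.45003807937393386
   },
   "FCA441": {
    "166": 0.31104217933103445,
    "170": 0.21548296050522298,
    "174": 0.47347486016374246
   },
   "FCA90": {
    "100": 0.3040430715009958,
    "104": 0.2630636096782966,
    "108": 0.20941226714674602,
    "112": 0.022638657753809383,
    "96": 0.20084239392015216
   }
  },
  "wild_oman": {
   "6HDZ635": {
    "146": 0.5802172901257158,
    "150": 0.4197827098742843,
    "154": 0.0
   },
   "6HDZ700": {
    "156": 0.6449243217645585,
    "160": 0.35507567823544145
   },
   "6HDZ89": {
    "136": 0.09701850866008684,
    "140": 0.9029814913399131
   },
   "FCA105": {
    "106": 0.3274856947330969,
    "110": 0.3393795212564821,
    "114": 0.0,
    "118": 0.333134784010421
   },
   "FCA126": {
    "116": 0.7550704713142884,
    "120": 0.024323274965311566,
    "124": 0.0,
    "128": 0.2206062537204002
   },
   "FCA279": {
    "126": 0.37425721518434485,
    "130": 0.0,
    "134": 0.08728508736684105,
    "138": 0.5384576974488141
   },
   "FCA441": {
    "166": 0.0,
    "170": 1.0,
    "174": 0.0
   },
   "FCA90": {
    "100": 0.38782473245698446,
    "104": 0.2081125812280872,
    "108": 0.4040626863149283,
    "112": 0.0,
    "96": 0.0
   }
  }
 },
 "loci": [
  "FCA90",
  "FCA105",
  "FCA126",
  "FCA279",
  "6HDZ89",
  "6HDZ635",
  "6HDZ700",
  "FCA441"
 ],
 "membership": {
  "6HDZ635": {
   "146": "shared",
   "150": "shared",
   "154": "captive_only"
  },
  "6HDZ700": {
   "156": "shared",
   "160": "shared"
  },
  "6HDZ89": {
   "136": "shared",
   "140": "shared"
  },
  "FCA105": {
   "106": "shared",
   "110": "shared",
   "114": "captive_only",
   "118": "shared"
  },
  "FCA126": {
   "116": "wild_only",
   "120": "shared",
   "124": "captive_only",
   "128": "shared"
  },
  "FCA279": {
   "126": "shared",
   "130": "captive_only",
   "134": "wild_only",
   "138": "shared"
  },
  "FCA441": {
   "166": "yemen_only",
   "170": "shared",
   "174": "captive_only"
  },
  "FCA90": {
   "100": "shared",
   "104": "shared",
   "108": "shared",
   "112": "captive_only",
   "96": "yemen_only"
  }
 }
}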