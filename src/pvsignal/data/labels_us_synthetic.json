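{
  "jurisdiction": "US",
  "comment": "Synthetic stand-in label reference for the worked example. Lists only the event terms the example needs; NOT an authoritative extract of any approved label.",
  "drugs": {
    "S01LA05": [
      "endophthalmitis",
      "muscae volitantes",
      "retinal detachment",
      "retinal haemorrhage",
      "intraocular pressure increased",
      "eye pain",
      "cataract",
      "conjunctival haemorrhage",
      "vitreous detachment"
    ],
    "S01LA04": [
      "retinal disorder",
      "endophthalmitis",
      "retinal detachment",
      "retinal haemorrhage",
      "vision abnormal",
      "conjunctivitis",
      "muscae volitantes",
      "conjunctival haemorrhage",
      "intraocular pressure increased",
      "eye pain",
      "vitreous detachment"
    ]
  }
}
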