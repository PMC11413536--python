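[
 {
  "codon": "000",
  "category": "PART",
  "kind": "SEGMENT"
 },
 {
  "codon": "001",
  "category": "PART",
  "kind": "SEGMENT"
 },
 {
  "codon": "002",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "003",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "010",
  "category": "PART",
  "kind": "NEURON"
 },
 {
  "codon": "011",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "012",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "013",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "020",
  "category": "PART",
  "kind": "WIRE"
 },
 {
  "codon": "021",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "022",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "023",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "030",
  "category": "MAGNITUDE",
  "attr": "size",
  "level": 1
 },
 {
  "codon": "031",
  "category": "MAGNITUDE",
  "attr": "size",
  "level": 2
 },
 {
  "codon": "032",
  "category": "MAGNITUDE",
  "attr": "size",
  "level": 3
 },
 {
  "codon": "033",
  "category": "MAGNITUDE",
  "attr": "size",
  "level": 4
 },
 {
  "codon": "100",
  "category": "PART",
  "kind": "SENSOR"
 },
 {
  "codon": "101",
  "category": "FEATURE",
  "kind": "sensor-output-1"
 },
 {
  "codon": "102",
  "category": "FEATURE",
  "kind": "sensor-output-2"
 },
 {
  "codon": "103",
  "category": "FEATURE",
  "kind": "sensor-output-3"
 },
 {
  "codon": "110",
  "category": "FEATURE",
  "kind": "sphere-sensor-x"
 },
 {
  "codon": "111",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "112",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "113",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "120",
  "category": "FEATURE",
  "kind": "sphere-sensor-z"
 },
 {
  "codon": "121",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "122",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "123",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "130",
  "category": "FEATURE",
  "kind": "wire-connections"
 },
 {
  "codon": "131",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "132",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "133",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "200",
  "category": "PART",
  "kind": "JOINT"
 },
 {
  "codon": "201",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "202",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "203",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "210",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "211",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "212",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "213",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "220",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "221",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "222",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "223",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "230",
  "category": "MAGNITUDE",
  "attr": "mounts",
  "level": 1
 },
 {
  "codon": "231",
  "category": "MAGNITUDE",
  "attr": "mounts",
  "level": 2
 },
 {
  "codon": "232",
  "category": "MAGNITUDE",
  "attr": "mounts",
  "level": 3
 },
 {
  "codon": "233",
  "category": "MAGNITUDE",
  "attr": "mounts",
  "level": 4
 },
 {
  "codon": "300",
  "category": "FEATURE",
  "kind": "joint"
 },
 {
  "codon": "301",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "302",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "303",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "310",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "311",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "312",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "313",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "320",
  "category": "MAGNITUDE",
  "attr": "connectors",
  "level": 1
 },
 {
  "codon": "321",
  "category": "MAGNITUDE",
  "attr": "connectors",
  "level": 2
 },
 {
  "codon": "322",
  "category": "MAGNITUDE",
  "attr": "connectors",
  "level": 3
 },
 {
  "codon": "323",
  "category": "MAGNITUDE",
  "attr": "connectors",
  "level": 4
 },
 {
  "codon": "330",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "331",
  "category": "FEATURE",
  "kind": "generic"
 },
 {
  "codon": "332",
  "category": "STOP"
 },
 {
  "codon": "333",
  "category": "START"
 }
]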