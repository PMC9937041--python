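{
 "jtt.json": "196ce23973c7df3e45b74f7e08ac1d3bc79e1072ec2446d672aaa5ceec282c98",
 "lg.json": "f33b80a409f19785b5050b7d0f03b533452e7c14a9d942f352c101bc9c60177a"
}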