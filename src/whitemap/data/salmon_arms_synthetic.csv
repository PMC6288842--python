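arm,chrom,start,end,class
Ssa1p,Ssa01,0,71000000,AORe
Ssa1qa,Ssa01,71000000,142000000,AORe
Ssa1qb,Ssa01,142000000,197000000,AORe
Ssa2p,Ssa02,0,82000000,LORe
Ssa2q,Ssa02,82000000,147000000,LORe
Ssa3p,Ssa03,0,61000000,mixed
Ssa3q,Ssa03,61000000,117000000,LORe
Ssa4p,Ssa04,0,44000000,LORe
Ssa4q,Ssa04,44000000,105000000,AORe
Ssa5p,Ssa05,0,63000000,mixed
Ssa5q,Ssa05,63000000,123000000,LORe
Ssa6p,Ssa06,0,27000000,LORe
Ssa6q,Ssa06,27000000,68000000,AORe
Ssa7p,Ssa07,0,40000000,AORe
Ssa7q,Ssa07,40000000,111000000,LORe
Ssa8q,Ssa08,0,54000000,LORe
Ssa9p,Ssa09,0,28000000,AORe
Ssa9qa,Ssa09,28000000,71000000,AORe
Ssa9qb,Ssa09,71000000,153000000,mixed
Ssa10p,Ssa10,0,69000000,AORe
Ssa10q,Ssa10,69000000,113000000,AORe
Ssa11qa,Ssa11,0,81000000,LORe
Ssa11qb,Ssa11,81000000,119000000,AORe
Ssa12qa,Ssa12,0,80000000,LORe
Ssa12qb,Ssa12,80000000,114000000,AORe
Ssa13qa,Ssa13,0,30000000,mixed
Ssa13qb,Ssa13,30000000,57000000,AORe
Ssa14qa,Ssa14,0,41000000,AORe
Ssa14qb,Ssa14,41000000,98000000,AORe
Ssa15qa,Ssa15,0,84000000,AORe
Ssa15qb,Ssa15,84000000,143000000,mixed
Ssa16qa,Ssa16,0,40000000,AORe
Ssa16qb,Ssa16,40000000,73000000,LORe
Ssa17qa,Ssa17,0,73000000,LORe
Ssa17qb,Ssa17,73000000,150000000,LORe
Ssa18qa,Ssa18,0,73000000,AORe
Ssa18qb,Ssa18,73000000,153000000,AORe
Ssa19qa,Ssa19,0,64000000,AORe
Ssa19qb,Ssa19,64000000,105000000,AORe
Ssa20qa,Ssa20,0,65000000,AORe
Ssa20qb,Ssa20,65000000,138000000,AORe
Ssa21,Ssa21,0,39000000,AORe
Ssa22,Ssa22,0,85000000,AORe
Ssa23,Ssa23,0,26000000,mixed
Ssa24,Ssa24,0,50000000,AORe
Ssa25,Ssa25,0,32000000,AORe
Ssa26,Ssa26,0,84000000,LORe
Ssa27,Ssa27,0,32000000,AORe
Ssa28,Ssa28,0,44000000,AORe
Ssa29,Ssa29,0,52000000,AORe
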